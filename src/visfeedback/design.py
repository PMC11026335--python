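"""Experimental design and synthetic voxel-pattern simulation.

The paradigm presents partially occluded indoor rooms; voxels that
retinotopically represent the occluded region receive no informative
feedforward input, so any stimulus information in their activity arrives as
*feedback*: contextual (the visible room surround) or mnemonic (the object
retrieved from memory through an episodic or semantic route).

The design couples 4 objects with 16 rooms: 8 rooms carry newly learned
(episodic) object pairings and 8 carry prior-knowledge (semantic) pairings,
each object appearing in exactly two rooms per set.  An occlusion session
consists of 4 runs × 96 trials (16 rooms × 6 repetitions, 4 s stimulus +
2 s ITI = 576 s/run); a sensory-template run shows the 16 un-occluded
pairings 12 times (1.5 s + 1 s ITI = 480 s).

The simulator generates single-trial response patterns directly at the β
level: each trial's voxel pattern is an additive mixture of a room-specific
(contextual) signature, an object-specific (mnemonic) signature, and i.i.d.
Gaussian noise.  Signatures are unit-norm so amplitudes read as SNR relative
to noise_sd = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigError, DataError

TRIAL_COLUMNS = ["run", "trial_index", "onset_s", "duration_s", "room", "object", "trial_type", "phase"]

OBJECTS = ("tv", "bed", "bathtub", "couch")
ROOMS = tuple(f"room{i:02d}" for i in range(1, 17))


@dataclass(frozen=True)
class StimulusSet:
    """4 objects × 16 rooms with episodic and semantic room→object pairing maps."""

    objects: tuple[str, ...]
    rooms: tuple[str, ...]
    episodic_pairs: Mapping[str, str]
    semantic_pairs: Mapping[str, str]

    def __post_init__(self) -> None:
        if len(self.objects) != 4 or len(set(self.objects)) != 4:
            raise ConfigError("need exactly 4 distinct objects")
        if len(self.rooms) != 16 or len(set(self.rooms)) != 16:
            raise ConfigError("need exactly 16 distinct rooms")
        epi, sem = set(self.episodic_pairs), set(self.semantic_pairs)
        if len(epi) != 8 or len(sem) != 8 or epi & sem:
            raise ConfigError("episodic and semantic room sets must be disjoint with 8 rooms each")
        if epi | sem != set(self.rooms):
            raise ConfigError("pairing maps must cover all 16 rooms")
        for pairs in (self.episodic_pairs, self.semantic_pairs):
            counts = pd.Series(list(pairs.values())).value_counts()
            if set(counts.index) != set(self.objects) or not (counts == 2).all():
                raise ConfigError("each object must appear in exactly 2 rooms per pairing set")

    def pairs(self, trial_type: str) -> Mapping[str, str]:
        if trial_type == "episodic":
            return self.episodic_pairs
        if trial_type == "semantic":
            return self.semantic_pairs
        raise ConfigError(f"unknown trial_type {trial_type!r}")

    def rooms_of(self, obj: str, trial_type: str) -> list[str]:
        """The (two) rooms paired with `obj` in the given set, sorted for determinism."""
        return sorted(r for r, o in self.pairs(trial_type).items() if o == obj)

    def room_object(self, room: str) -> tuple[str, str]:
        """Return (object, trial_type) for a room."""
        if room in self.episodic_pairs:
            return self.episodic_pairs[room], "episodic"
        if room in self.semantic_pairs:
            return self.semantic_pairs[room], "semantic"
        raise DataError(f"room {room!r} not in stimulus set")


@dataclass(frozen=True)
class GroundTruthParams:
    """Generating parameters for one simulated group.

    Amplitudes are in noise-SD units (signatures are unit-norm).  w_ctx scales
    the room signature on occlusion trials, w_mne_epi / w_mne_sem the object
    signature depending on the retrieval route, and w_ff replaces both on
    sensory-template (feedforward) trials.
    """

    group: str = "younger"
    n_voxels: int = 50
    w_ctx: float = 1.0
    w_mne_epi: float = 0.3
    w_mne_sem: float = 0.05
    w_ff: float = 1.0
    noise_sd: float = 1.0
    signature_seed: int = 0
    orthogonalize: bool = True

    def __post_init__(self) -> None:
        if self.n_voxels < 2:
            raise ConfigError("n_voxels must be >= 2")
        for name in ("w_ctx", "w_mne_epi", "w_mne_sem", "w_ff", "noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")


@dataclass
class SubjectPatterns:
    """Trial × voxel matrix of single-trial response estimates with labels."""

    subject: str
    group: str
    roi: str
    data: np.ndarray
    trial_table: pd.DataFrame
    truth: GroundTruthParams | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise DataError("pattern matrix must be 2-D (trials × voxels)")
        if self.data.shape[0] != len(self.trial_table):
            raise DataError(
                f"pattern rows ({self.data.shape[0]}) != trial table rows ({len(self.trial_table)})"
            )
        if not np.isfinite(self.data).all():
            raise DataError("pattern matrix contains non-finite entries")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]

    @property
    def phase(self) -> str:
        phases = self.trial_table["phase"].unique()
        return phases[0] if len(phases) == 1 else "mixed"


def make_stimulus_set(seed: int = 0) -> StimulusSet:
    """Randomly assign rooms to objects under the 2-rooms-per-object constraint.

    The 16 rooms are split into an episodic and a semantic half; within each
    half every object is paired with exactly two rooms, the assignment
    shuffled by `seed`.
    """
    rng = np.random.default_rng(seed)
    rooms = list(ROOMS)
    rng.shuffle(rooms)
    episodic_rooms, semantic_rooms = rooms[:8], rooms[8:]

    def assign(room_half: list[str]) -> dict[str, str]:
        objs = list(OBJECTS) * 2
        rng.shuffle(objs)
        return dict(zip(sorted(room_half), objs))

    return StimulusSet(
        objects=OBJECTS,
        rooms=ROOMS,
        episodic_pairs=assign(episodic_rooms),
        semantic_pairs=assign(semantic_rooms),
    )


def _schedule(
    stim: StimulusSet,
    room_sequence_per_run: list[list[str]],
    stim_dur: float,
    iti: float,
    phase: str,
) -> pd.DataFrame:
    if stim_dur <= 0 or iti < 0:
        raise ConfigError("stimulus duration must be positive and ITI non-negative")
    rows = []
    for run_idx, seq in enumerate(room_sequence_per_run, start=1):
        for k, room in enumerate(seq):
            obj, trial_type = stim.room_object(room)
            rows.append(
                {
                    "run": run_idx,
                    "trial_index": k,
                    "onset_s": k * (stim_dur + iti),
                    "duration_s": stim_dur,
                    "room": room,
                    "object": obj,
                    "trial_type": trial_type,
                    "phase": phase,
                }
            )
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def make_occlusion_schedule(
    stim: StimulusSet,
    n_runs: int = 4,
    reps: int = 6,
    stim_dur: float = 4.0,
    iti: float = 2.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Occlusion-task trial table: per run, every room `reps` times in shuffled order."""
    if n_runs < 1 or reps < 1:
        raise ConfigError("n_runs and reps must be >= 1")
    rng = np.random.default_rng(seed)
    sequences = []
    for _ in range(n_runs):
        seq = list(stim.rooms) * reps
        rng.shuffle(seq)
        sequences.append(seq)
    return _schedule(stim, sequences, stim_dur, iti, phase="occlusion")


def make_sensory_schedule(
    stim: StimulusSet,
    reps: int = 12,
    stim_dur: float = 1.5,
    iti: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Sensory-template trial table: one run of the 16 pairings × `reps`, un-occluded."""
    if reps < 1:
        raise ConfigError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    seq = list(stim.rooms) * reps
    rng.shuffle(seq)
    return _schedule(stim, [seq], stim_dur, iti, phase="sensory")


def run_duration(schedule: pd.DataFrame, run: int | None = None) -> float:
    """Total run duration implied by the onset grid (last offset + ITI)."""
    df = schedule if run is None else schedule[schedule["run"] == run]
    if df.empty:
        raise DataError("empty schedule")
    onsets = df["onset_s"].to_numpy()
    if len(onsets) > 1:
        spacing = onsets[1] - onsets[0]
    else:
        spacing = df["duration_s"].iloc[0]
    return float(onsets[-1] + spacing)


def make_signatures(truth: GroundTruthParams) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Draw the subject's fixed unit-norm room and object signature vectors.

    By default the 16 room and 4 object signatures are jointly orthogonalized
    (QR), so neither accidental room–room collinearity nor room–object overlap
    can confound recovery: with raw Gaussian directions, the chance overlap of
    an object signature with room signatures injects a per-subject bias of
    order w_ctx·w_mne/√n_voxels into every object-level statistic.  Requires
    n_voxels >= 20; with orthogonalize=False raw directions are used.
    """
    rng = np.random.default_rng(truth.signature_seed)
    n_sig = len(ROOMS) + len(OBJECTS)
    mat = rng.standard_normal((truth.n_voxels, n_sig))
    if truth.orthogonalize:
        if truth.n_voxels < n_sig:
            raise ConfigError(
                f"orthogonalized signatures need n_voxels >= {n_sig}; got {truth.n_voxels}"
            )
        q, r = np.linalg.qr(mat)
        mat = q * np.sign(np.diag(r))  # sign-fix so the draw is rotation-stable
    mat = (mat / np.linalg.norm(mat, axis=0, keepdims=True)).T  # n_sig × voxels
    rooms = {room: mat[i] for i, room in enumerate(ROOMS)}
    objects = {obj: mat[len(ROOMS) + i] for i, obj in enumerate(OBJECTS)}
    return rooms, objects


def simulate_subject_patterns(
    truth: GroundTruthParams,
    schedule: pd.DataFrame,
    seed: int,
    subject: str = "sub-01",
    roi: str = "V1",
) -> SubjectPatterns:
    """Simulate single-trial β patterns for one subject/ROI on a schedule.

    Occlusion trials:  β = w_ctx·s_room + w_mne(route)·s_object + ε
    Sensory trials:    β = w_ff·s_room + w_ff·s_object + ε
    with ε ~ N(0, noise_sd²) i.i.d. per voxel and trial; signatures are fixed
    per subject (drawn from truth.signature_seed).
    """
    if schedule.empty:
        raise DataError("schedule is empty")
    room_sigs, obj_sigs = make_signatures(truth)
    rng = np.random.default_rng(seed)
    n = len(schedule)
    data = rng.standard_normal((n, truth.n_voxels)) * truth.noise_sd
    w_mne = {"episodic": truth.w_mne_epi, "semantic": truth.w_mne_sem}
    for i, row in enumerate(schedule.itertuples(index=False)):
        if row.phase == "sensory":
            data[i] += truth.w_ff * room_sigs[row.room] + truth.w_ff * obj_sigs[row.object]
        else:
            data[i] += truth.w_ctx * room_sigs[row.room] + w_mne[row.trial_type] * obj_sigs[row.object]
    return SubjectPatterns(
        subject=subject, group=truth.group, roi=roi, data=data,
        trial_table=schedule.reset_index(drop=True), truth=truth,
    )


def subject_seed_sequence(cohort_seed: int, group_index: int, subject_index: int) -> np.random.SeedSequence:
    """Counter-based per-subject seed stream: stable under adding subjects or groups."""
    return np.random.SeedSequence(entropy=cohort_seed, spawn_key=(group_index, subject_index))


def make_cohort(
    group_params: Mapping[str, GroundTruthParams],
    n_per_group: int,
    seed: int,
    stim: StimulusSet | None = None,
    occlusion: pd.DataFrame | None = None,
    sensory: pd.DataFrame | None = None,
    rois: Sequence[str] = ("V1", "V2"),
    between_subject_sd: float = 0.0,
    ff_mne_rho: float = 0.0,
) -> list[SubjectPatterns]:
    """Simulate a cohort: per subject and ROI, one occlusion and one sensory pattern set.

    All subjects share the schedule (as in a real study); each subject gets its
    own signature and noise streams derived from `seed` by counter-based
    splitting, so adding subjects never perturbs existing ones.

    With between_subject_sd > 0, each subject's feedforward (w_ff) and episodic
    mnemonic (w_mne_epi) amplitudes are jittered around the group values by a
    bivariate Gaussian with correlation `ff_mne_rho` (truncated at 0), giving
    ground-truth coupling between feedforward fidelity and episodic feedback
    strength for recovery studies.
    """
    if n_per_group < 1:
        raise ConfigError("n_per_group must be >= 1")
    if stim is None:
        stim = make_stimulus_set(seed=seed)
    if occlusion is None:
        occlusion = make_occlusion_schedule(stim, seed=seed)
    if sensory is None:
        sensory = make_sensory_schedule(stim, seed=seed)

    out: list[SubjectPatterns] = []
    for g_idx, (group, base) in enumerate(sorted(group_params.items())):
        for s_idx in range(n_per_group):
            ss = subject_seed_sequence(seed, g_idx, s_idx)
            sig_seed, amp_seed, *roi_seeds = ss.spawn(2 + 2 * len(rois))
            truth = replace(base, group=group, signature_seed=int(sig_seed.generate_state(1)[0] % (2**31)))
            if between_subject_sd > 0:
                arng = np.random.default_rng(amp_seed)
                cov = [[1.0, ff_mne_rho], [ff_mne_rho, 1.0]]
                a, b = arng.multivariate_normal([0, 0], cov)
                truth = replace(
                    truth,
                    w_ff=max(base.w_ff + between_subject_sd * a, 0.0),
                    w_mne_epi=max(base.w_mne_epi + between_subject_sd * b, 0.0),
                )
            subject = f"sub-{group}-{s_idx:03d}"
            for r_idx, roi in enumerate(rois):
                occ_seed, sen_seed = roi_seeds[2 * r_idx].generate_state(1)[0], roi_seeds[2 * r_idx + 1].generate_state(1)[0]
                out.append(simulate_subject_patterns(truth, occlusion, int(occ_seed % (2**31)), subject, roi))
                out.append(simulate_subject_patterns(truth, sensory, int(sen_seed % (2**31)), subject, roi))
    return out
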