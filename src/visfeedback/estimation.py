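"""BOLD time-series simulation and least-squares-separate (LSS) single-trial GLMs.

This is the optional "realistic" entry point: instead of handing simulated β
patterns straight to decoding/RSA, a schedule plus per-trial β patterns can be
rendered into BOLD runs (boxcar ⊛ canonical double-gamma HRF, low-frequency
drift, Gaussian noise) and the β patterns re-estimated one trial at a time.

Each LSS model contains one regressor for the target trial, sixteen per-room
regressors built from all *other* trials' onsets (the target trial is removed
from its room's regressor — with it left in, the pair would be exactly
collinear), the nuisance columns, cosine drift terms, and an intercept.  The
target regressor's coefficient is that trial's β row.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import SubjectPatterns, run_duration
from .exceptions import ConfigError, DataError

#: default high-pass cutoff for the cosine drift basis, seconds
HP_CUTOFF_S = 128.0


@dataclass
class BoldRun:
    """One run's BOLD matrix (timepoints × voxels) on a fixed TR grid."""

    data: np.ndarray
    tr: float
    run: int

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ConfigError("tr must be positive")
        self.data = np.asarray(self.data, dtype=float)

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]


@dataclass
class NuisanceSet:
    """Nuisance regressor matrix (timepoints × k) with column labels."""

    data: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.shape[1] != len(self.labels):
            raise DataError("nuisance column count does not match labels")


DEFAULT_NUISANCE_LABELS = [
    "trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z",
    "global_signal", "white_matter", "csf",
]


def make_nuisance(n_timepoints: int, seed: int = 0, labels: list[str] | None = None) -> NuisanceSet:
    """Synthetic nuisance table: smooth random walks standing in for head-motion
    and compartment-intensity traces (6 motion + 3 intensity columns by default)."""
    labels = labels if labels is not None else list(DEFAULT_NUISANCE_LABELS)
    rng = np.random.default_rng(seed)
    steps = rng.standard_normal((n_timepoints, len(labels))) * 0.01
    return NuisanceSet(np.cumsum(steps, axis=0), labels)


def hrf_kernel(tr: float, duration: float = 32.0) -> np.ndarray:
    """Canonical double-gamma haemodynamic response sampled every `tr` seconds.

    Peak response ~5 s post-onset with an undershoot around 15 s; amplitude
    normalized to a unit peak.  Zero at t = 0.
    """
    if tr <= 0:
        raise ConfigError("tr must be positive")
    t = np.arange(np.ceil(duration / tr) + 1) * tr
    h = stats.gamma.pdf(t, 6) - stats.gamma.pdf(t, 16) / 6.0
    return h / h.max()


def _cosine_drift_basis(n_timepoints: int, tr: float, cutoff_s: float = HP_CUTOFF_S) -> np.ndarray:
    """Discrete cosine high-pass basis (frequencies below 1/cutoff)."""
    duration = n_timepoints * tr
    n_basis = int(np.floor(2 * duration / cutoff_s))
    t = (np.arange(n_timepoints) + 0.5) / n_timepoints
    cols = [np.cos(np.pi * k * t) for k in range(1, n_basis + 1)]
    return np.column_stack(cols) if cols else np.empty((n_timepoints, 0))


def trial_regressors(
    run_schedule: pd.DataFrame, tr: float, n_timepoints: int, oversample: int = 10
) -> np.ndarray:
    """HRF-convolved boxcar regressor for every trial of one run (timepoints × trials).

    Built on an oversampled grid (tr/oversample) and sampled back onto the TR
    grid, so onsets that do not fall on TR multiples are resampled rather than
    truncated.  The same function drives both simulation and LSS fitting.
    """
    dt = tr / oversample
    n_fine = n_timepoints * oversample
    kernel = hrf_kernel(dt)
    out = np.empty((n_timepoints, len(run_schedule)))
    for j, row in enumerate(run_schedule.itertuples(index=False)):
        box = np.zeros(n_fine)
        a = int(round(row.onset_s / dt))
        b = min(int(round((row.onset_s + row.duration_s) / dt)), n_fine)
        if a >= n_fine:
            raise DataError(f"trial onset {row.onset_s} s beyond run end")
        box[a:b] = 1.0
        conv = np.convolve(box, kernel)[:n_fine]
        out[:, j] = conv[::oversample]
    return out


def simulate_bold(
    schedule: pd.DataFrame,
    patterns: SubjectPatterns,
    tr: float = 0.8,
    drift_amp: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[BoldRun]:
    """Render β patterns into per-run BOLD time series.

    Each voxel's series is Σ_trials β·(boxcar ⊛ HRF) plus `drift_amp`-scaled
    low-frequency cosine drift with random coefficients and N(0, noise_sd²)
    noise.
    """
    if len(schedule) != patterns.n_trials:
        raise DataError("schedule and patterns are not aligned")
    rng = np.random.default_rng(seed)
    runs = []
    for run in sorted(schedule["run"].unique()):
        mask = (schedule["run"] == run).to_numpy()
        run_sched = schedule[mask]
        n_tp = int(np.ceil(run_duration(schedule, run) / tr))
        x = trial_regressors(run_sched, tr, n_tp)
        y = x @ patterns.data[mask]
        if drift_amp > 0:
            basis = _cosine_drift_basis(n_tp, tr)
            if basis.shape[1]:
                y += basis @ (rng.standard_normal((basis.shape[1], y.shape[1])) * drift_amp)
        if noise_sd > 0:
            y += rng.standard_normal(y.shape) * noise_sd
        runs.append(BoldRun(y, tr=tr, run=int(run)))
    return runs


def _check_rank(design: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify near-dependent columns from the QR diagonal
        _, r = np.linalg.qr(design)
        diag = np.abs(np.diag(r))
        bad = [names[i] for i in np.where(diag < 1e-8 * diag.max())[0]]
        raise DataError(f"rank-deficient LSS design; collinear columns: {bad or names}")


def fit_lss(
    bold_runs: list[BoldRun],
    schedule: pd.DataFrame,
    nuisance: NuisanceSet | list[NuisanceSet] | None = None,
    hp_cutoff_s: float = HP_CUTOFF_S,
) -> SubjectPatterns:
    """Least-squares-separate estimation of single-trial β patterns.

    One GLM per trial: target-trial regressor, 16 room regressors (the target
    removed from its own room's regressor), nuisance columns, cosine drifts,
    intercept.  Returns patterns in schedule order.
    """
    run_ids = sorted(schedule["run"].unique())
    if len(bold_runs) != len(run_ids):
        raise DataError("number of BOLD runs does not match schedule")
    if isinstance(nuisance, NuisanceSet):
        nuisance = [nuisance] * len(bold_runs)

    n_voxels = bold_runs[0].data.shape[1]
    betas = np.empty((len(schedule), n_voxels))
    rooms = sorted(schedule["room"].unique())

    for run_pos, (run, bold) in enumerate(zip(run_ids, bold_runs)):
        mask = (schedule["run"] == run).to_numpy()
        run_sched = schedule[mask].reset_index(drop=True)
        x_trials = trial_regressors(run_sched, bold.tr, bold.n_timepoints)
        room_of = run_sched["room"].to_numpy()
        room_cols = {rm: x_trials[:, room_of == rm].sum(axis=1) for rm in rooms}

        drift = _cosine_drift_basis(bold.n_timepoints, bold.tr, hp_cutoff_s)
        extra = [drift, np.ones((bold.n_timepoints, 1))]
        extra_names = [f"drift{k}" for k in range(drift.shape[1])] + ["intercept"]
        if nuisance is not None:
            nui = nuisance[run_pos]
            if nui.data.shape[0] != bold.n_timepoints:
                raise DataError("nuisance rows do not match BOLD timepoints")
            extra.insert(0, nui.data)
            extra_names = nui.labels + extra_names
        extra_mat = np.column_stack(extra)

        row_indices = np.where(mask)[0]
        for t in range(len(run_sched)):
            target = x_trials[:, t]
            room_block = np.column_stack([
                room_cols[rm] - (target if rm == room_of[t] else 0.0) for rm in rooms
            ])
            # a room whose only trial is the target leaves an all-zero column; drop it
            keep = np.linalg.norm(room_block, axis=0) > 1e-12
            design = np.column_stack([target[:, None], room_block[:, keep], extra_mat])
            names = ["target"] + [f"room:{rm}" for rm, k in zip(rooms, keep) if k] + extra_names
            _check_rank(design, names)
            coefs, *_ = np.linalg.lstsq(design, bold.data, rcond=None)
            betas[row_indices[t]] = coefs[0]

    return SubjectPatterns(
        subject="lss", group="", roi="", data=betas,
        trial_table=schedule.reset_index(drop=True),
    )
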