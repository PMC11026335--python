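"""Representational similarity analysis: trialwise RDMs, model RDMs, model fits.

Occlusion-task RDMs use the cross-validated Mahalanobis (crossnobis)
distance; sensory-template RDMs use Pearson correlation distance (1 − r).
Crossnobis is unbiased — its expectation is zero when two conditions share a
true pattern — so entries may be negative, and the magnitude is directly
interpretable as pattern discriminability.

Cross-validation requires independent partitions, so crossnobis is computed
between *condition* (room) estimates — the per-run mean of that room's
trials — across all ordered run pairs, and the condition-level distance is
assigned back to every trial pair with those rooms.  As a consequence,
off-diagonal pairs of the same room are exactly zero in trial mode.

Two binary model RDMs encode the ideal dissimilarity structure of each
feedback component; both are rank-correlated (Spearman) with the neural RDM
over the included upper-triangle cells, and the coefficient is Fisher-z
transformed for group-level inference (Wilcoxon signed-rank against zero).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import SubjectPatterns
from .exceptions import ConfigError, DataError

#: cap |rho| below 1 so the Fisher transform stays finite
_RHO_CAP = 1.0 - 1e-12

RDM_LABEL_COLUMNS = ["room", "object", "trial_type", "run"]


@dataclass
class RDM:
    """Square trialwise (or conditionwise) dissimilarity matrix with labels."""

    values: np.ndarray
    labels: pd.DataFrame  # one row per matrix row: room, object, trial_type, run
    metric: str  # "crossnobis" | "pearson_distance"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise DataError("RDM must be square")
        if len(self.labels) != n:
            raise DataError("RDM labels do not match matrix size")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise DataError("RDM must be symmetric")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def subset(self, mask: np.ndarray) -> "RDM":
        idx = np.where(mask)[0]
        return RDM(self.values[np.ix_(idx, idx)], self.labels.iloc[idx].reset_index(drop=True), self.metric)


@dataclass
class ModelRDM:
    """Binary ideal-dissimilarity matrix with an inclusion mask.

    contextual: 0 where both trials show the same room (same object follows),
    1 elsewhere; only the diagonal is excluded.
    mnemonic: 0 for same object–different room, 1 for different objects;
    same-room pairs are excluded so that room similarity cannot deflate the
    object-based dissimilarity structure; diagonal excluded.
    """

    values: np.ndarray
    include: np.ndarray  # bool mask of cells entering the correlation
    kind: str  # "contextual" | "mnemonic"
    labels: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.shape != self.include.shape:
            raise DataError("model matrix and mask shapes differ")
        if np.any(np.diag(self.include)):
            raise DataError("diagonal must be excluded")


@dataclass
class ModelFit:
    """Spearman fit of one model RDM to one neural RDM."""

    rho: float
    z: float
    model: str
    trial_type: str
    n_cells: int
    subject: str = ""
    group: str = ""
    roi: str = ""


def _noise_precision(residuals: np.ndarray, method: str, shrinkage: float) -> np.ndarray:
    """Inverse noise covariance from within-run, within-condition residuals."""
    n, v = residuals.shape
    if method == "identity":
        return np.eye(v)
    s = residuals.T @ residuals / max(n - 1, 1)
    if method == "diag":
        d = np.diag(s).copy()
        if np.any(d <= 0):
            raise DataError("zero-variance voxel; cannot invert diagonal covariance")
        return np.diag(1.0 / d)
    if method == "shrinkage":
        s = (1.0 - shrinkage) * s + shrinkage * np.diag(np.diag(s))
    elif method != "sample":
        raise ConfigError(f"unknown noise covariance method {method!r}")
    try:
        l = np.linalg.cholesky(s)
    except np.linalg.LinAlgError as err:
        raise DataError(
            "noise covariance is singular; use noise_cov='shrinkage' (or 'diag'/'identity')"
        ) from err
    eye = np.eye(v)
    return np.linalg.solve(l.T, np.linalg.solve(l, eye))


def crossnobis_rdm(
    patterns: SubjectPatterns,
    noise_cov: str = "shrinkage",
    shrinkage: float = 0.5,
    mode: str = "trials",
) -> RDM:
    """Cross-validated Mahalanobis RDM over rooms, expanded to trial pairs.

    For rooms c, d the distance is the mean over ordered run pairs (A, B),
    A ≠ B, of (x̂_cA − x̂_dA)ᵀ Σ⁻¹ (x̂_cB − x̂_dB) / n_voxels, with x̂ the
    per-run room-mean pattern and Σ the noise covariance estimated from
    within-run, within-room residuals ('shrinkage' toward its diagonal by
    default; 'identity' reduces to cross-validated Euclidean).

    mode="trials" returns the matrix over one run's trial layout (96 × 96 for
    the default design); mode="conditions" returns the 16 × 16 room matrix.
    """
    tt = patterns.trial_table
    runs = sorted(tt["run"].unique())
    if len(runs) < 2:
        raise DataError("crossnobis needs at least 2 runs")
    rooms = sorted(tt["room"].unique())
    v = patterns.n_voxels

    means = np.empty((len(runs), len(rooms), v))
    residuals = []
    for a, run in enumerate(runs):
        for c, room in enumerate(rooms):
            rows = patterns.data[((tt["run"] == run) & (tt["room"] == room)).to_numpy()]
            if rows.shape[0] == 0:
                raise DataError(f"room {room!r} missing from run {run}")
            means[a, c] = rows.mean(axis=0)
            residuals.append(rows - means[a, c])
    prec = _noise_precision(np.vstack(residuals), noise_cov, shrinkage)

    dist = np.zeros((len(rooms), len(rooms)))
    n_pairs = 0
    for a in range(len(runs)):
        for b in range(len(runs)):
            if a == b:
                continue
            # delta[c] - delta[d] for all pairs via pairwise difference of room means
            da = means[a][:, None, :] - means[a][None, :, :]
            db = means[b][:, None, :] - means[b][None, :, :]
            dist += np.einsum("cdv,vw,cdw->cd", da, prec, db)
            n_pairs += 1
    dist /= n_pairs * v

    if mode == "conditions":
        labels = pd.DataFrame(
            {
                "room": rooms,
                "object": [_room_obj(tt, r)[0] for r in rooms],
                "trial_type": [_room_obj(tt, r)[1] for r in rooms],
                "run": 0,
            }
        )
        return RDM((dist + dist.T) / 2, labels, "crossnobis")
    if mode != "trials":
        raise ConfigError(f"unknown matrix mode {mode!r}")

    template = tt[tt["run"] == runs[0]].reset_index(drop=True)
    room_idx = template["room"].map({r: i for i, r in enumerate(rooms)}).to_numpy()
    trial_mat = dist[np.ix_(room_idx, room_idx)]
    labels = template[["room", "object", "trial_type", "run"]].copy()
    return RDM((trial_mat + trial_mat.T) / 2, labels, "crossnobis")


def _room_obj(tt: pd.DataFrame, room: str) -> tuple[str, str]:
    row = tt[tt["room"] == room].iloc[0]
    return row["object"], row["trial_type"]


def pearson_rdm(patterns: SubjectPatterns) -> RDM:
    """Correlation-distance RDM: entry (i, j) = 1 − Pearson r of trial rows i, j."""
    if patterns.n_voxels < 2:
        raise DataError("pearson_rdm needs at least 2 voxels")
    sd = patterns.data.std(axis=1)
    bad = np.where(sd == 0)[0]
    if len(bad):
        raise DataError(f"zero-variance trial row(s) {bad.tolist()}; correlation undefined")
    values = 1.0 - np.corrcoef(patterns.data)
    np.fill_diagonal(values, 0.0)
    labels = patterns.trial_table[["room", "object", "trial_type", "run"]].reset_index(drop=True)
    return RDM((values + values.T) / 2, labels, "pearson_distance")


def build_model_rdm(labels: pd.DataFrame, kind: str, trial_type: str | None = None) -> ModelRDM:
    """Binary ideal-pattern matrix and exclusion mask for one feedback component.

    `labels` must carry room and object per trial (an RDM's label frame or a
    trial table).  With `trial_type` given, the model is restricted to trials
    of that type (cells involving the other type are excluded, not dropped,
    so the matrix stays aligned with the full neural RDM).
    """
    if kind not in ("contextual", "mnemonic"):
        raise ConfigError(f"unknown model kind {kind!r}")
    labels = labels.reset_index(drop=True)
    room = labels["room"].to_numpy()
    obj = labels["object"].to_numpy()
    same_room = room[:, None] == room[None, :]
    same_obj = obj[:, None] == obj[None, :]
    n = len(labels)

    include = ~np.eye(n, dtype=bool)
    if kind == "contextual":
        values = np.where(same_room, 0.0, 1.0)
    else:
        values = np.where(same_obj & ~same_room, 0.0, 1.0)
        include &= ~same_room  # same-room similarity must not deflate the object structure
    if trial_type is not None:
        in_type = (labels["trial_type"] == trial_type).to_numpy()
        include &= in_type[:, None] & in_type[None, :]
    np.fill_diagonal(values, 0.0)
    return ModelRDM(values, include, kind, labels)


def fit_model(neural: RDM, model: ModelRDM) -> ModelFit:
    """Spearman rank correlation between neural and model dissimilarities.

    Computed over the included upper-triangle cells only (the matrices are
    symmetric); rho is Fisher-z transformed with |rho| capped just below 1.
    """
    if neural.values.shape != model.values.shape:
        raise DataError("neural and model RDM sizes differ")
    if not neural.labels[["room", "object"]].equals(model.labels[["room", "object"]]):
        raise DataError("neural and model RDM trial orderings differ")
    triu = np.triu(np.ones_like(model.include, dtype=bool), k=1)
    cells = model.include & triu
    n_cells = int(cells.sum())
    if n_cells < 3:
        raise DataError("fewer than 3 included cells")
    rho = stats.spearmanr(neural.values[cells], model.values[cells]).statistic
    rho_c = float(np.clip(rho, -_RHO_CAP, _RHO_CAP))
    tts = model.labels.loc[cells.any(axis=1), "trial_type"].unique()
    return ModelFit(
        rho=float(rho),
        z=float(np.arctanh(rho_c)),
        model=model.kind,
        trial_type=tts[0] if len(tts) == 1 else "all",
        n_cells=n_cells,
    )


def wilcoxon_vs_zero(values: np.ndarray, alternative: str = "greater") -> tuple[float, float]:
    """Wilcoxon signed-rank test of a sample against zero.

    Exact null for n ≤ 25 (no ties/zeros), normal approximation with
    continuity correction otherwise.
    """
    values = np.asarray(values, dtype=float)
    nonzero = values[values != 0]
    if len(nonzero) == 0:
        raise DataError("all values are zero; signed-rank test undefined")
    ties = len(np.unique(np.abs(nonzero))) < len(nonzero)
    method = "exact" if len(nonzero) <= 25 and not ties and len(nonzero) == len(values) else "approx"
    res = stats.wilcoxon(values, alternative=alternative, method=method, correction=(method == "approx"))
    return float(res.statistic), float(res.pvalue)
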