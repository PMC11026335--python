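"""Differentiation indices (DI) and the feedforward–feedback coupling analysis.

The DI measures the specificity of object representations: the mean
dissimilarity between trials of *different* objects minus the mean
dissimilarity between trials of the *same* object.  Higher DI = better
differentiated representations; age-related dedifferentiation shows up as
lower DIs.  Feedback DIs come from the occlusion-task crossnobis RDMs (one
per trial type); the feedforward DI comes from the sensory-template Pearson
RDM (a single value per subject and ROI, the template run makes no
episodic/semantic distinction).

Downstream, DIs are z-scored within stratum, |z| > 3.29 outliers (the most
extreme 0.1% of a normal) are excluded, and feedforward DIs are Spearman
correlated (one-sided) with each feedback DI per group × ROI × trial type,
with Benjamini–Hochberg correction across the family.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import islice, permutations

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigError, DataError
from .rsa import RDM

OUTLIER_SD = 3.29  # two-sided normal tail beyond this ≈ 0.1%

DI_COLUMNS = ["subject", "group", "roi", "trial_type", "pathway", "di", "z_di", "outlier"]


@dataclass
class DIRecord:
    """One differentiation index for a subject × pathway × trial type × ROI."""

    subject: str
    group: str
    roi: str
    trial_type: str  # episodic | semantic | all
    pathway: str  # feedforward | feedback
    di: float
    z_di: float = math.nan
    outlier: bool = False


def differentiation_index(
    rdm: RDM, trial_type: str | None = None, pair_policy: str = "different_room"
) -> float:
    """mean(between-object dissimilarity) − mean(within-object dissimilarity).

    pair_policy "different_room" (default) counts only same-object pairs from
    different rooms as within — same-room pairs are excluded so that room
    similarity cannot inflate within-object similarity, mirroring the
    mnemonic model's exclusion.  "include_all" counts every same-object pair.
    """
    if pair_policy not in ("different_room", "include_all"):
        raise ConfigError(f"unknown pair_policy {pair_policy!r}")
    labels = rdm.labels
    keep = np.ones(rdm.n, dtype=bool)
    if trial_type is not None:
        keep &= (labels["trial_type"] == trial_type).to_numpy()
    idx = np.where(keep)[0]
    room = labels["room"].to_numpy()[idx]
    obj = labels["object"].to_numpy()[idx]
    vals = rdm.values[np.ix_(idx, idx)]

    same_obj = obj[:, None] == obj[None, :]
    same_room = room[:, None] == room[None, :]
    triu = np.triu(np.ones_like(same_obj, dtype=bool), k=1)
    within = same_obj & triu
    if pair_policy == "different_room":
        within &= ~same_room
    between = ~same_obj & triu
    if not within.any() or not between.any():
        raise DataError("no within or between pairs left after filtering")
    return float(vals[between].mean() - vals[within].mean())


def zscore_and_flag_outliers(
    records: pd.DataFrame,
    threshold: float = OUTLIER_SD,
    strata: tuple[str, ...] = ("group", "roi", "pathway", "trial_type"),
) -> pd.DataFrame:
    """Standardize DIs within stratum and flag |z| > threshold as outliers.

    Strata default to the per-group, per-ROI, per-pathway, per-trial-type
    splits; pass e.g. ("roi", "pathway", "trial_type") for group-pooled
    z-scoring.
    """
    df = records.copy()
    for key, sub in df.groupby(list(strata)):
        if len(sub) < 2:
            raise DataError(f"stratum {key} has fewer than 2 records")
        sd = sub["di"].std(ddof=1)
        if sd == 0:
            df.loc[sub.index, "z_di"] = 0.0
        else:
            df.loc[sub.index, "z_di"] = (sub["di"] - sub["di"].mean()) / sd
    df["outlier"] = df["z_di"].abs() > threshold
    return df


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, alternative: str) -> float:
    """Exact permutation p for Spearman's rho by enumerating pairings of y."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx_c = rx - rx.mean()
    denom = np.linalg.norm(rx_c) * np.linalg.norm(ry - ry.mean())
    if denom == 0:
        raise DataError("constant ranks; correlation undefined")
    ry_c = ry - ry.mean()
    observed = float(rx_c @ ry_c / denom)
    count = total = 0
    it = permutations(ry_c)
    chunk_size = 40320
    while True:
        chunk = list(islice(it, chunk_size))
        if not chunk:
            break
        rhos = np.asarray(chunk) @ rx_c / denom
        total += len(rhos)
        if alternative == "greater":
            count += int(np.sum(rhos >= observed - 1e-12))
        elif alternative == "less":
            count += int(np.sum(rhos <= observed + 1e-12))
        else:
            count += int(np.sum(np.abs(rhos) >= abs(observed) - 1e-12))
    return count / total


def spearman_test(
    x: np.ndarray, y: np.ndarray, alternative: str = "greater", exact_max_n: int = 10
) -> tuple[float, float]:
    """Spearman rho with exact-permutation p for small n, asymptotic otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise DataError("need >= 3 paired observations")
    rho = float(stats.spearmanr(x, y).statistic)
    if len(x) <= exact_max_n:
        p = _exact_spearman_p(x, y, alternative)
    else:
        p = float(stats.spearmanr(x, y, alternative=alternative).pvalue)
    return rho, p


def ff_fb_correlation(
    records: pd.DataFrame, alternative: str = "greater", exact_max_n: int = 10
) -> pd.DataFrame:
    """Correlate feedforward with feedback DIs per group × ROI × trial type.

    `records` is a tidy DI table (see DI_COLUMNS) with z_di/outlier filled in;
    flagged outliers are dropped, subjects are paired, and a one-sided
    Spearman test is run per stratum.  Returns a tidy frame with raw and
    BH-adjusted p-values.
    """
    clean = records[~records["outlier"]]
    ff = clean[clean["pathway"] == "feedforward"].set_index(["subject", "group", "roi"])["di"]
    fb = clean[clean["pathway"] == "feedback"]
    rows = []
    for (group, roi, trial_type), sub in fb.groupby(["group", "roi", "trial_type"]):
        pairs = []
        for _, rec in sub.iterrows():
            key = (rec["subject"], group, roi)
            if key in ff.index:
                pairs.append((ff.loc[key], rec["di"]))
        if len(pairs) < 3:
            raise DataError(f"fewer than 3 complete pairs in stratum {(group, roi, trial_type)}")
        arr = np.array(pairs)
        rho, p = spearman_test(arr[:, 0], arr[:, 1], alternative, exact_max_n)
        rows.append(
            {"group": group, "roi": roi, "trial_type": trial_type,
             "n": len(pairs), "rho": rho, "p": p}
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    return out


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (order-preserving)."""
    pvals = np.asarray(pvals, dtype=float)
    if np.any((pvals < 0) | (pvals > 1)):
        raise DataError("p-values must lie in [0, 1]")
    return stats.false_discovery_control(pvals, method="bh")
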