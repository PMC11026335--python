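"""File-format dialects: trial tables (CSV), pattern matrices (TSV + JSON sidecar).

All formats are plain text.  A subject's pattern set is a tab-separated
trial × voxel matrix next to a JSON sidecar holding subject, group, ROI,
phase and (when simulated) the generating parameters, so every matrix on
disk is self-describing and shape-checked on read.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .design import TRIAL_COLUMNS, GroundTruthParams, SubjectPatterns
from .exceptions import DataError


def write_trial_table(table: pd.DataFrame, path: str | Path) -> None:
    table[TRIAL_COLUMNS].to_csv(path, index=False)


def read_trial_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing column(s) {missing}")
    df = df[TRIAL_COLUMNS]
    for run, sub in df.groupby("run"):
        onsets = sub["onset_s"].to_numpy()
        if np.any(np.diff(onsets) <= 0):
            raise DataError(f"{path}: onsets not strictly increasing within run {run}")
        if sub["trial_index"].duplicated().any():
            raise DataError(f"{path}: duplicated trial_index in run {run}")
    return df.reset_index(drop=True)


def _sidecar_path(matrix_path: Path) -> Path:
    return matrix_path.with_suffix(".json")


def write_patterns(patterns: SubjectPatterns, path: str | Path) -> None:
    """Write matrix as TSV and a JSON sidecar; the trial table goes alongside."""
    path = Path(path)
    np.savetxt(path, patterns.data, delimiter="\t")
    meta = {
        "subject": patterns.subject,
        "group": patterns.group,
        "roi": patterns.roi,
        "phase": patterns.phase,
        "n_trials": patterns.n_trials,
        "n_voxels": patterns.n_voxels,
        "trial_table": path.stem + ".trials.csv",
        "truth": dataclasses.asdict(patterns.truth) if patterns.truth else None,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    write_trial_table(patterns.trial_table, path.parent / meta["trial_table"])


def read_patterns(path: str | Path) -> SubjectPatterns:
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise DataError(f"missing sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    data = np.loadtxt(path, delimiter="\t", ndmin=2)
    if data.shape != (meta["n_trials"], meta["n_voxels"]):
        raise DataError(
            f"{path}: matrix shape {data.shape} does not match sidecar "
            f"({meta['n_trials']}, {meta['n_voxels']})"
        )
    table = read_trial_table(path.parent / meta["trial_table"])
    truth = GroundTruthParams(**meta["truth"]) if meta.get("truth") else None
    return SubjectPatterns(
        subject=meta["subject"], group=meta["group"], roi=meta["roi"],
        data=data, trial_table=table, truth=truth,
    )


def pattern_filename(subject: str, roi: str, phase: str) -> str:
    return f"{subject}_{roi}_{phase}.tsv"
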