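"""End-to-end orchestration: simulate → (estimate) → decode → RSA → DI → report.

A validated `PipelineConfig` fully determines a run: cohort parameters per
group, schedule geometry, estimation mode (direct β patterns or
BOLD-simulation + LSS), decoding/RSA/DI settings, and a master seed.  Seeds
for every stage are derived from the master seed by counter-based
`SeedSequence` splitting, so the pipeline is bit-reproducible in direct-β
mode and adding subjects never perturbs existing ones.

All outputs are tidy tables (one observation per row), ready for external
mixed-model fitting, plus a JSON manifest (config hash, seed, version).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import pydantic

from . import __version__
from .decoding import (
    ClassifierConfig,
    build_contextual_scheme,
    build_mnemonic_scheme,
    bootstrap_significant,
    group_bootstrap_test,
    group_ttest,
    permutation_null,
    run_loro_cv,
)
from .design import (
    GroundTruthParams,
    StimulusSet,
    SubjectPatterns,
    make_cohort,
    make_occlusion_schedule,
    make_sensory_schedule,
    make_stimulus_set,
)
from .differentiation import ff_fb_correlation, differentiation_index, zscore_and_flag_outliers
from .estimation import fit_lss, make_nuisance, simulate_bold
from .exceptions import ConfigError
from .io import pattern_filename, write_patterns
from .rsa import build_model_rdm, crossnobis_rdm, fit_model, pearson_rdm, wilcoxon_vs_zero

#: default generating parameters per simulated age group.  "older" mirrors the
#: qualitative empirical pattern: weaker contextual and feedforward signal,
#: preserved episodic mnemonic signal, stronger semantic mnemonic signal,
#: higher noise.
DEFAULT_GROUP_PRESETS: dict[str, dict] = {
    "younger": dict(n_voxels=50, w_ctx=1.4, w_mne_epi=0.45, w_mne_sem=0.05,
                    w_ff=1.0, noise_sd=1.0),
    "older": dict(n_voxels=50, w_ctx=1.0, w_mne_epi=0.45, w_mne_sem=0.25,
                  w_ff=0.6, noise_sd=1.2),
}


class _Model(pydantic.BaseModel):
    model_config = pydantic.ConfigDict(extra="forbid")


class GroupParams(_Model):
    n_voxels: int = pydantic.Field(50, ge=2)
    w_ctx: float = pydantic.Field(1.0, ge=0)
    w_mne_epi: float = pydantic.Field(0.3, ge=0)
    w_mne_sem: float = pydantic.Field(0.05, ge=0)
    w_ff: float = pydantic.Field(1.0, ge=0)
    noise_sd: float = pydantic.Field(1.0, ge=0)
    orthogonalize: bool = True


class ScheduleConfig(_Model):
    n_runs: int = pydantic.Field(4, ge=2)
    reps: int = pydantic.Field(6, ge=1)
    stim_dur: float = pydantic.Field(4.0, gt=0)
    iti: float = pydantic.Field(2.0, ge=0)
    sensory_reps: int = pydantic.Field(12, ge=1)
    sensory_stim_dur: float = pydantic.Field(1.5, gt=0)
    sensory_iti: float = pydantic.Field(1.0, ge=0)


class BoldConfig(_Model):
    tr: float = pydantic.Field(0.8, gt=0)
    drift_amp: float = pydantic.Field(0.0, ge=0)
    noise_sd: float = pydantic.Field(0.0, ge=0)


class DecodingConfig(_Model):
    n_perm: int = pydantic.Field(100, ge=1)
    n_boot: int = pydantic.Field(1000, ge=1)
    C: float = pydantic.Field(1.0, gt=0)
    zscore: bool = False
    percentile: float = pydantic.Field(99.9, gt=0, lt=100)


class RsaConfig(_Model):
    noise_cov: Literal["shrinkage", "diag", "identity", "sample"] = "shrinkage"
    shrinkage: float = pydantic.Field(0.5, ge=0, le=1)
    matrix_mode: Literal["trials", "conditions"] = "trials"


class DiConfig(_Model):
    pair_policy: Literal["different_room", "include_all"] = "different_room"
    outlier_threshold: float = pydantic.Field(3.29, gt=0)


class PipelineConfig(_Model):
    groups: dict[str, GroupParams] = pydantic.Field(
        default_factory=lambda: {g: GroupParams(**p) for g, p in DEFAULT_GROUP_PRESETS.items()}
    )
    n_per_group: int = pydantic.Field(10, ge=1)
    rois: list[str] = ["V1", "V2"]
    schedule: ScheduleConfig = ScheduleConfig()
    estimation_mode: Literal["direct-beta", "bold-lss"] = "direct-beta"
    bold: BoldConfig = BoldConfig()
    decoding: DecodingConfig = DecodingConfig()
    rsa: RsaConfig = RsaConfig()
    di: DiConfig = DiConfig()
    between_subject_sd: float = pydantic.Field(0.0, ge=0)
    ff_mne_rho: float = pydantic.Field(0.0, ge=-1, le=1)
    seed: int = 0
    out_dir: str | None = None

    @classmethod
    def load(cls, source: str | Path | dict) -> "PipelineConfig":
        """Build a config from a dict or JSON file; schema violations raise ConfigError."""
        try:
            if isinstance(source, dict):
                return cls(**source)
            return cls(**json.loads(Path(source).read_text()))
        except pydantic.ValidationError as err:
            raise ConfigError(str(err)) from err

    def truth(self, group: str) -> GroundTruthParams:
        return GroundTruthParams(group=group, **self.groups[group].model_dump())


@dataclass
class ResultBundle:
    """Per-stage tidy tables plus a reproducibility manifest."""

    tables: dict[str, pd.DataFrame]
    manifest: dict
    out_dir: Path | None = None


def _stage_seed(master: int, *key: int) -> int:
    return int(np.random.SeedSequence(entropy=master, spawn_key=key).generate_state(1)[0] % (2**31))


def config_hash(config: PipelineConfig) -> str:
    return hashlib.sha256(
        json.dumps(config.model_dump(mode="json"), sort_keys=True).encode()
    ).hexdigest()[:16]


def simulate_cohort(config: PipelineConfig) -> tuple[StimulusSet, list[SubjectPatterns]]:
    """Stage 1: design + cohort simulation (and LSS re-estimation if configured)."""
    stim = make_stimulus_set(seed=config.seed)
    sched = config.schedule
    occlusion = make_occlusion_schedule(
        stim, sched.n_runs, sched.reps, sched.stim_dur, sched.iti, seed=config.seed
    )
    sensory = make_sensory_schedule(
        stim, sched.sensory_reps, sched.sensory_stim_dur, sched.sensory_iti, seed=config.seed
    )
    subjects = make_cohort(
        {g: config.truth(g) for g in config.groups},
        config.n_per_group,
        seed=config.seed,
        stim=stim,
        occlusion=occlusion,
        sensory=sensory,
        rois=config.rois,
        between_subject_sd=config.between_subject_sd,
        ff_mne_rho=config.ff_mne_rho,
    )
    if config.estimation_mode == "bold-lss":
        subjects = [_reestimate(sp, i, config) for i, sp in enumerate(subjects)]
    return stim, subjects


def _reestimate(sp: SubjectPatterns, index: int, config: PipelineConfig) -> SubjectPatterns:
    seed = _stage_seed(config.seed, 1, index)
    runs = simulate_bold(
        sp.trial_table, sp, tr=config.bold.tr,
        drift_amp=config.bold.drift_amp, noise_sd=config.bold.noise_sd, seed=seed,
    )
    nuisance = [make_nuisance(r.n_timepoints, seed=seed + k) for k, r in enumerate(runs)]
    est = fit_lss(runs, sp.trial_table, nuisance)
    return SubjectPatterns(
        subject=sp.subject, group=sp.group, roi=sp.roi,
        data=est.data, trial_table=sp.trial_table, truth=sp.truth,
    )


def decode_cohort(
    stim: StimulusSet, subjects: list[SubjectPatterns], config: PipelineConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stage 2: both schemes × both trial types per subject/ROI + group bootstrap."""
    clf = ClassifierConfig(C=config.decoding.C, zscore=config.decoding.zscore)
    schemes = {
        ("contextual", tt): build_contextual_scheme(stim, tt) for tt in ("episodic", "semantic")
    } | {
        ("mnemonic_crossclass", tt): build_mnemonic_scheme(stim, tt)
        for tt in ("episodic", "semantic")
    }
    rows, nulls = [], {}
    occ = [s for s in subjects if s.phase == "occlusion"]
    for i, sp in enumerate(occ):
        for j, ((kind, tt), spec_list) in enumerate(sorted(schemes.items())):
            res = run_loro_cv(sp, spec_list, clf)
            null = permutation_null(
                sp, spec_list, n_perm=config.decoding.n_perm,
                seed=_stage_seed(config.seed, 2, i, j), config=clf,
            )
            nulls[(sp.group, sp.roi, tt, kind, sp.subject)] = null
            for fold, acc in enumerate(res.fold_accuracies):
                rows.append(
                    {"subject": sp.subject, "group": sp.group, "roi": sp.roi,
                     "trial_type": tt, "scheme": kind, "fold": fold,
                     "accuracy": float(acc), "n_problems": res.n_problems}
                )
    table = pd.DataFrame(rows)

    group_rows = []
    subj_mean = table.groupby(["group", "roi", "trial_type", "scheme", "subject"])["accuracy"].mean()
    for k, (group, roi, tt, kind) in enumerate(sorted({idx[:4] for idx in subj_mean.index})):
        accs = subj_mean.loc[group, roi, tt, kind]
        subject_nulls = [
            null for (g, r, t, s, _), null in nulls.items()
            if (g, r, t, s) == (group, roi, tt, kind)
        ]
        observed = float(accs.mean())
        null_means, p_boot = group_bootstrap_test(
            subject_nulls, observed, n_boot=config.decoding.n_boot,
            seed=_stage_seed(config.seed, 3, k),
        )
        t_stat, p_t = group_ttest(accs.to_numpy())
        group_rows.append(
            {"group": group, "roi": roi, "trial_type": tt, "scheme": kind,
             "n_subjects": len(accs), "mean_accuracy": observed, "p_boot": p_boot,
             "significant": bootstrap_significant(null_means, observed, config.decoding.percentile),
             "t": t_stat, "p_t": p_t}
        )
    return table, pd.DataFrame(group_rows)


def rsa_cohort(
    subjects: list[SubjectPatterns], config: PipelineConfig
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Stage 3: crossnobis RDMs, model fits, Wilcoxon group tests.

    Returns (fits table, group table, rdms dict keyed by (subject, roi, phase)).
    """
    fit_rows = []
    rdms: dict[tuple[str, str, str], object] = {}
    for sp in subjects:
        if sp.phase == "occlusion":
            rdm = crossnobis_rdm(
                sp, noise_cov=config.rsa.noise_cov, shrinkage=config.rsa.shrinkage,
                mode=config.rsa.matrix_mode,
            )
            rdms[(sp.subject, sp.roi, "occlusion")] = rdm
            for model_kind in ("contextual", "mnemonic"):
                for tt in ("episodic", "semantic"):
                    model = build_model_rdm(rdm.labels, model_kind, trial_type=tt)
                    fit = fit_model(rdm, model)
                    fit_rows.append(
                        {"subject": sp.subject, "group": sp.group, "roi": sp.roi,
                         "trial_type": tt, "model": model_kind,
                         "rho": fit.rho, "z": fit.z, "n_cells": fit.n_cells}
                    )
        else:
            rdms[(sp.subject, sp.roi, "sensory")] = pearson_rdm(sp)
    fits = pd.DataFrame(fit_rows)
    group_rows = []
    for (group, roi, tt, model), sub in fits.groupby(["group", "roi", "trial_type", "model"]):
        stat, p = wilcoxon_vs_zero(sub["z"].to_numpy(), alternative="greater")
        group_rows.append(
            {"group": group, "roi": roi, "trial_type": tt, "model": model,
             "n_subjects": len(sub), "mean_z": float(sub["z"].mean()),
             "wilcoxon_stat": stat, "p": p}
        )
    return fits, pd.DataFrame(group_rows), rdms


def di_cohort(
    subjects: list[SubjectPatterns], rdms: dict, config: PipelineConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stage 4: feedback + feedforward DIs, outlier flagging, ff–fb correlation."""
    rows = []
    for sp in subjects:
        if sp.phase == "occlusion":
            rdm = rdms[(sp.subject, sp.roi, "occlusion")]
            for tt in ("episodic", "semantic"):
                di = differentiation_index(rdm, trial_type=tt, pair_policy=config.di.pair_policy)
                rows.append(
                    {"subject": sp.subject, "group": sp.group, "roi": sp.roi,
                     "trial_type": tt, "pathway": "feedback", "di": di}
                )
        else:
            rdm = rdms[(sp.subject, sp.roi, "sensory")]
            di = differentiation_index(rdm, pair_policy=config.di.pair_policy)
            rows.append(
                {"subject": sp.subject, "group": sp.group, "roi": sp.roi,
                 "trial_type": "all", "pathway": "feedforward", "di": di}
            )
    table = zscore_and_flag_outliers(pd.DataFrame(rows), threshold=config.di.outlier_threshold)
    corr = ff_fb_correlation(table, alternative="greater")
    return table, corr


def run_pipeline(config: PipelineConfig | dict) -> ResultBundle:
    """Execute all stages in dependency order and optionally persist the bundle."""
    if isinstance(config, dict):
        config = PipelineConfig.load(config)
    t0 = time.time()
    stim, subjects = simulate_cohort(config)
    decoding_table, decoding_group = decode_cohort(stim, subjects, config)
    model_fits, model_group, rdms = rsa_cohort(subjects, config)
    di_table, di_corr = di_cohort(subjects, rdms, config)
    tables = {
        "decoding": decoding_table,
        "decoding_group": decoding_group,
        "model_fits": model_fits,
        "model_fits_group": model_group,
        "di": di_table,
        "di_correlations": di_corr,
    }
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": config.model_dump(mode="json"),
        "config_hash": config_hash(config),
        "estimation_mode": config.estimation_mode,
        "aggregation": "unweighted mean over binary problems and folds",
        "di_pair_policy": config.di.pair_policy,
        "rsa_matrix_mode": config.rsa.matrix_mode,
        "n_rows": {name: len(df) for name, df in tables.items()},
        "runtime_s": round(time.time() - t0, 2),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(out_dir / f"{name}.csv", index=False)
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return ResultBundle(tables=tables, manifest=manifest, out_dir=out_dir)


def write_cohort(subjects: list[SubjectPatterns], out_dir: str | Path) -> list[Path]:
    """Persist a simulated cohort (one TSV + sidecar per subject/ROI/phase)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for sp in subjects:
        path = out_dir / pattern_filename(sp.subject, sp.roi, sp.phase)
        write_patterns(sp, path)
        paths.append(path)
    return paths


def summarize(bundle: ResultBundle) -> str:
    """Human-readable summary of a result bundle's group-level tables."""
    lines = [f"visfeedback {bundle.manifest['version']} — seed {bundle.manifest['seed']}"]
    dg = bundle.tables["decoding_group"]
    lines.append("\nDecoding (group means, chance = 0.50):")
    for _, r in dg.iterrows():
        sig = "*" if r["significant"] else " "
        lines.append(
            f"  {r['group']:>8} {r['roi']} {r['trial_type'][:3]} {r['scheme']:<20}"
            f" acc={r['mean_accuracy']:.3f}{sig} p_boot={r['p_boot']:.3f}"
        )
    mg = bundle.tables["model_fits_group"]
    lines.append("\nModel-RDM fits (mean Fisher z, Wilcoxon vs 0):")
    for _, r in mg.iterrows():
        lines.append(
            f"  {r['group']:>8} {r['roi']} {r['trial_type'][:3]} {r['model']:<10}"
            f" z={r['mean_z']:+.3f} p={r['p']:.4f}"
        )
    dc = bundle.tables["di_correlations"]
    lines.append("\nFeedforward–feedback DI correlations (one-sided Spearman, BH-adjusted):")
    for _, r in dc.iterrows():
        lines.append(
            f"  {r['group']:>8} {r['roi']} {r['trial_type'][:3]}"
            f" rho={r['rho']:+.3f} p={r['p']:.3f} p_adj={r['p_adj']:.3f} (n={r['n']})"
        )
    return "\n".join(lines)
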