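# Methods

This note documents the models, estimators and numerical choices behind
`visfeedback`, and what the synthetic-data validation does and does not
establish about real data.

## Generative model

Each subject × ROI is simulated at the single-trial β level. A trial showing
room *r* paired with object *o* produces the voxel pattern

    occlusion phase:  β = w_ctx·s_r + w_mne(route)·s_o + ε
    sensory phase:    β = w_ff·s_r + w_ff·s_o + ε

with ε i.i.d. N(0, noise_sd²) per voxel and trial. Signatures `s` are fixed
per subject, unit-norm, and drawn from the subject's `signature_seed`.
Amplitudes are therefore in noise-SD units: `w_ctx = 1` means the contextual
pattern difference between two rooms has the magnitude of one noise SD per
voxel dimension.

**Joint orthogonalization.** By default the 16 room and 4 object signatures
are orthogonalized together (one QR decomposition; requires ≥ 20 voxels).
With raw Gaussian directions, chance overlap between an object signature and
the room set injects a per-subject bias of order `w_ctx·w_mne/√n_voxels`
into every object-level statistic (mnemonic model fit, DI). At 50 voxels
this geometry noise is comparable to the mnemonic signal itself
(`2·w_mne²/n_voxels`) and would dominate subject-to-subject variance, so the
simulation would measure signature geometry rather than the estimators.
`orthogonalize=False` restores raw directions for studies of that confound.

**Group presets.** Defaults live in `DEFAULT_GROUP_PRESETS`
(`pipeline.py`); they were calibrated so that the analysis stack reproduces
the canonical result pattern at cohort scale:

| parameter | younger | older | consequence |
|---|---|---|---|
| w_ctx | 1.4 | 1.0 | contextual accuracy ≈ 0.69 vs ≈ 0.58 |
| w_mne_epi | 0.45 | 0.45 | episodic mnemonic-model z ≈ 0.09, preserved across groups |
| w_mne_sem | 0.05 | 0.25 | semantic feedback weak in younger, stronger in older |
| w_ff | 1.0 | 0.6 | feedforward DI lower in older |
| noise_sd | 1.0 | 1.2 | overall dedifferentiation in older |

**Trial order** is a seeded uniform shuffle of the 16 rooms × reps per run.
Design-efficiency optimization matters only when estimating from BOLD with
overlapping responses; the β-level simulator bypasses it, and the LSS path
is validated for recovery rather than efficiency.

**Between-subject structure.** `make_cohort` can jitter each subject's
feedforward and episodic-mnemonic amplitudes with a truncated bivariate
Gaussian (`between_subject_sd`, `ff_mne_rho`), giving a known ground-truth
coupling between feedforward fidelity and episodic feedback strength for
recovery studies. Subject seeds derive from the cohort seed by counter-based
`SeedSequence` spawning, so enlarging a cohort never changes existing
subjects.

## Single-trial estimation (optional BOLD path)

`simulate_bold` renders β patterns into per-run time series: boxcar ⊛
canonical double-gamma HRF (peak ≈ 5 s, undershoot ≈ 15 s, unit peak),
sampled on a TR grid via 10× oversampling, plus low-frequency cosine drift
and Gaussian noise. `fit_lss` estimates one GLM per trial: the target-trial
regressor, sixteen room regressors built from the remaining trials (the
target is removed from its own room's regressor — leaving it in makes the
pair exactly collinear), the nuisance columns (6 motion + 3 compartment
intensities by default, accepted as a precomputed table), cosine drift
columns (128 s cutoff) and an intercept. The intercept and drift columns are
additions beyond the minimal regressor list; without them the β contract
would depend on pre-filtering. Noiseless round-trips recover β to < 1e-6
because trials of the same room share a true pattern when pattern noise is
zero, so the truth lies in the design span.

## Decoding

Binary linear SVMs with fixed C = 1 and no feature scaling by default
(β maps share units; per-fold z-scoring is a flag). The contextual scheme
builds one problem per object (its two rooms within a trial type are the
classes; train and test cells identical). The mnemonic scheme
cross-classifies: per object pair, train on one room per object, test on
each object's other room, both assignment directions — 12 problems whose
train and test rooms are disjoint, so only object information can transfer.
Subject-level accuracy is the unweighted mean over problems, then folds
(fourfold leave-one-run-out). The choice of unweighted averaging over all
admissible problems is recorded in the result manifest.

The SVM dual is solved by an internal SMO routine (`_svm.py`) with
max-violating-pair selection and the standard 1e-3 KKT tolerance — the same
optimization problem libsvm solves, jitted with numba because the
permutation/bootstrap machinery refits millions of ~40-sample classifiers.
The test suite pins its predictions to scikit-learn's `SVC` on a broad set
of random problems.

Group-level inference is the two-step procedure: per subject, trial labels
are permuted within run (within train/test role for cross-classification,
preserving exchangeability under run-wise CV) and the full CV is recomputed,
100 times by default; at the group level one accuracy per subject is drawn
with replacement and averaged, 1,000 times, and the observed group mean is
compared with the 99.9th percentile of that null. A one-sided one-sample
t test against 0.5 is provided alongside.

## RSA

Occlusion RDMs use the cross-validated Mahalanobis distance. Because
cross-validation needs independent partitions, distances are computed
between per-run room-mean patterns across all ordered run pairs,

    d(c,d) = mean over (A,B), A≠B of (x̂_cA − x̂_dA)ᵀ Σ⁻¹ (x̂_cB − x̂_dB) / n_voxels,

and assigned back to trial pairs; in trial mode the matrix spans one run's
96-trial layout and same-room off-diagonal pairs are exactly zero. The
estimator is unbiased (expectation zero under pattern equality), so entries
may be negative. Σ is estimated from within-run, within-room residuals and
shrunk halfway toward its diagonal by default; `identity` reduces the metric
to cross-validated Euclidean (used by the oracle tests), and a singular
unshrunk covariance raises an explicit error. A 16 × 16 condition mode is
also available. Sensory-template RDMs are 1 − Pearson r between trial rows.

Model RDMs are binary. Contextual: 0 for same-room cells, 1 elsewhere,
diagonal excluded. Mnemonic: 0 for same-object–different-room, 1 for
different-object, with all same-room cells excluded so room similarity
cannot deflate the object structure. Fits are Spearman correlations over the
included upper-triangle cells (the matrices are symmetric; the lower
triangle adds nothing); ρ = ±1 is capped at ±(1 − 1e-12) before the Fisher
transform so z stays finite. Group-level: Wilcoxon signed-rank against zero,
exact for n ≤ 25 without ties, normal approximation with continuity
correction otherwise.

A note on sensitivity: with condition-matched fold estimates the 96 × 96
trial matrix contains only 16·15/2 distinct values, so a within-trial-type
model fit effectively ranks 28 room-pair values (4 same-object vs 24
different-object for the mnemonic model). Per-subject fit variability is
therefore bounded below (z SD ≈ 0.15) regardless of noise level, and
cohort-level inference leans on the subject dimension. A trialwise variant
(single trials against held-out-run condition means) was evaluated and was
not more sensitive; the condition-matched form is retained.

## Differentiation indices

DI = mean between-object dissimilarity − mean within-object dissimilarity,
computed per trial type for feedback (occlusion crossnobis RDM) and once per
subject × ROI for feedforward (sensory Pearson RDM). The default
`pair_policy="different_room"` excludes same-room pairs from the within set,
mirroring the mnemonic model's exclusion — with condition-matched crossnobis
those cells are structural zeros and would bias the within mean;
`include_all` implements the literal all-same-object-pairs reading. The
policy in force is recorded in output metadata.

DIs are z-scored within group × ROI × pathway × trial-type strata (a
group-pooled option exists) and |z| > 3.29 is flagged — the two-sided normal
tail beyond 3.29 SD is 0.1%. Outliers are excluded from the feedforward–
feedback Spearman correlations (one-sided, positive direction per
hypothesis), which use an exact permutation null for n ≤ 10 (vectorized
enumeration of pairings) and the asymptotic p otherwise, with
Benjamini–Hochberg adjustment across the group × ROI × trial-type family
(delegated to `scipy.stats.false_discovery_control`, cross-checked against a
brute-force step-up in the tests).

## What the validation shows — and does not

The suite verifies, on cohorts from the generative model above: exact design
arithmetic; chance-level calibration of the decoding stack on zero-signal
cohorts (mean accuracy 0.50 ± 0.02; two-step bootstrap rejection ≤ 7.5% at
the α = 0.05 analogue over 200 fresh 20-subject cohorts); the double
dissociation (contextual-only signal drives only the contextual scheme,
object-only signal only the cross-classification scheme); crossnobis
unbiasedness by Monte Carlo; exact-test agreement with full enumeration;
LSS recovery; monotonicity of model-fit z in the generating amplitudes; and
≥ 80% power to recover a generating feedforward–episodic coupling of
Spearman ρ ≈ 0.5 at n = 40.

Problem sizes in the suite are scaled for a single CPU: the calibration and
selectivity checks use 12 label permutations per subject (the pipeline
default remains 100) and 16–50 voxels; the power study runs at a favorable
SNR (48 voxels, noise SD 0.5) so that estimation attenuation does not mask
the procedure's statistical behavior.

The generator is deliberately minimal: additive signatures, i.i.d. Gaussian
noise, no spatial autocorrelation, no physiological noise, no
hemodynamic nonlinearity, no trial-order optimization, and an abstract voxel
set instead of retinotopically mapped ROIs. Passing tests certify the
estimators and inference machinery, not the biological claims; effect sizes
on real data depend on noise structure the simulation does not emulate. One
structural consequence worth noting: in this additive model any mnemonic
amplitude strong enough for RSA detection at cohort scale also lifts
cross-classification accuracy slightly (to ≈ 0.51), so the empirical
pattern "RSA detects object information where decoding entirely fails" can
be reproduced only as a sensitivity gap, not as a strict null — the demo
checks assert an at-chance accuracy band (|mean − 0.5| < 0.03) for the
mnemonic scheme rather than bootstrap non-significance.

## Numerical and degenerate-input conventions

* Rank-deficient LSS designs raise an error naming the collinear columns
  (QR-diagonal screen); all-zero room regressors (a room whose only trial is
  the target) are dropped instead.
* Zero-variance trial rows make Pearson distances undefined and raise with
  the trial index; zero-variance DI strata raise rather than emitting NaN z.
* Model fits require ≥ 3 included cells; Spearman/Wilcoxon tests require
  non-degenerate inputs and raise otherwise.
* SVM decisions at exactly 0 classify as class A; fold accuracies are exact
  fractions, and the fold average is unweighted.
* All stage seeds derive from the master seed via `SeedSequence` spawn keys;
  the result manifest records config hash, seed and version, and two runs
  with the same config and seed produce identical tables in direct-β mode.
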