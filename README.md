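# visfeedback

Decomposition of **feedback signals in non-stimulated early visual cortex**:
multivariate decoding, representational similarity analysis (RSA), and
differentiation-index statistics for occlusion-paradigm fMRI designs, with a
fully specified synthetic-cohort generator for validation and power studies.

## The problem

When part of a visual scene is occluded, the V1/V2 voxels whose receptive
fields fall inside the occluded region receive no informative feedforward
input — yet their activity carries stimulus information arriving through
lateral and top-down connections. Two feedback components can be separated
by design:

* **contextual feedback** — information about the visible surround (which
  *room* image frames the occluder), and
* **mnemonic feedback** — the *object* retrieved from memory upon seeing the
  room, through either a newly learned (**episodic**) or a prior-knowledge
  (**semantic**) route.

The design couples 4 objects with 16 rooms (8 episodic + 8 semantic
pairings, each object in exactly two rooms per set). An occlusion session
has 4 runs × 96 trials (16 rooms × 6 repetitions, 4 s + 2 s ITI = 576 s per
run); a sensory-template run shows the 16 un-occluded pairings 12 times
(1.5 s + 1 s = 480 s) to measure the feedforward analogue. Questions about
cohort differences (e.g., age-related dedifferentiation) reduce to comparing
these components across groups.

Because single-subject fMRI data for such designs are rarely shareable, the
package ships a generative model of the whole experiment: each trial's
voxel pattern is

```
β(trial) = w_ctx · s_room + w_mne(route) · s_object + ε,   ε ~ N(0, noise_sd²)
```

with unit-norm signature vectors `s` fixed per subject, so every analysis in
the stack can be validated against known ground truth.

## The analysis stack

| stage | method |
|---|---|
| single-trial estimation | least-squares-separate (LSS) GLM: one model per trial (target regressor + 16 room regressors + nuisance + drifts) on simulated BOLD (double-gamma HRF, TR 0.8 s) |
| contextual decoding | linear SVM (C = 1), classes = two rooms sharing an object; fourfold leave-one-run-out CV |
| mnemonic decoding | cross-classification: train on "different object–different room", test on disjoint rooms sharing the objects — only object information can transfer |
| group inference | two-step nonparametric test: 100 within-run label permutations per subject, then 1,000 bootstrap draws of group-mean accuracies; significant when the observed mean exceeds the 99.9th null percentile |
| RSA | cross-validated Mahalanobis (crossnobis) RDMs for occlusion runs (unbiased, may be negative), Pearson-distance RDMs for the sensory run |
| model fits | binary contextual / mnemonic model RDMs (with the "same object–same room" exclusion) rank-correlated (Spearman) with neural RDMs; Fisher-z; Wilcoxon signed-rank vs 0 |
| differentiation index | DI = mean between-object − mean within-object dissimilarity; z-scoring with the 3.29 SD outlier rule; one-sided Spearman coupling of feedforward and feedback DIs with Benjamini–Hochberg correction |

## Worked example

```bash
cat > demo.json <<'EOF'
{
 "n_per_group": 10,
 "rois": ["V1"],
 "decoding": {"n_perm": 50, "n_boot": 1000},
 "seed": 42,
 "out_dir": "demo_bundle"
}
EOF
visfeedback run-all --config demo.json
```

runs the full pipeline (simulate → decode → RSA → DI) for two simulated
groups of 10 subjects with the default presets and prints (~40 s on one CPU):

```
visfeedback 0.1.0 — seed 42

Decoding (group means, chance = 0.50):
     older V1 epi contextual           acc=0.564* p_boot=0.000
     older V1 epi mnemonic_crossclass  acc=0.521* p_boot=0.001
     older V1 sem contextual           acc=0.598* p_boot=0.000
     older V1 sem mnemonic_crossclass  acc=0.481  p_boot=0.997
   younger V1 epi contextual           acc=0.681* p_boot=0.000
   younger V1 epi mnemonic_crossclass  acc=0.504  p_boot=0.279
   younger V1 sem contextual           acc=0.696* p_boot=0.000
   younger V1 sem mnemonic_crossclass  acc=0.503  p_boot=0.374

Model-RDM fits (mean Fisher z, Wilcoxon vs 0):
     older V1 epi contextual z=+0.468 p=0.0029
     older V1 epi mnemonic   z=+0.073 p=0.0375
     older V1 sem contextual z=+0.473 p=0.0028
     older V1 sem mnemonic   z=-0.029 p=0.5940
   younger V1 epi contextual z=+0.597 p=0.0010
   younger V1 epi mnemonic   z=+0.018 p=0.4392
   younger V1 sem contextual z=+0.597 p=0.0010
   younger V1 sem mnemonic   z=-0.040 p=0.7239

Feedforward–feedback DI correlations (one-sided Spearman, BH-adjusted):
     older V1 epi rho=+0.285 p=0.214 p_adj=0.421 (n=10)
     older V1 sem rho=-0.115 p=0.633 p_adj=0.633 (n=10)
   younger V1 epi rho=+0.176 p=0.316 p_adj=0.421 (n=10)
   younger V1 sem rho=+0.358 p=0.156 p_adj=0.421 (n=10)
```

Reading the output: contextual decoding is far above chance in both groups
and weaker in the "older" preset (lower `w_ctx`, higher noise), while
mnemonic cross-decoding hovers at chance — at n = 10 per group individual
cells fluctuate (the older-episodic cell happens to cross the threshold
here). The contextual model RDM fits are strongly positive everywhere; the
mnemonic model fit is positive for episodic trials and near zero or negative
for semantic trials in the "younger" preset (`w_mne_sem = 0.05`). The DI
correlations are underpowered at n = 10 and serve as format illustration;
the test suite demonstrates calibrated power at n = 40.

Tidy per-subject tables (`decoding.csv`, `model_fits.csv`, `di.csv`, …) and
a manifest land in `demo_bundle/`; `visfeedback report demo_bundle` reprints
the summary. The CLI also exposes `simulate`, `estimate` (BOLD + LSS
round-trip), `decode`, `rsa` and `di` as individual stages, all driven by
the same JSON config and `--seed`.

Library use mirrors the CLI:

```python
import visfeedback as vf

stim = vf.make_stimulus_set(seed=0)
schedule = vf.make_occlusion_schedule(stim)          # 4 × 96 trials
truth = vf.GroundTruthParams(w_ctx=1.0, w_mne_epi=0.4, noise_sd=1.0)
subject = vf.simulate_subject_patterns(truth, schedule, seed=1)
result = vf.run_loro_cv(subject, vf.build_contextual_scheme(stim, "episodic"))
print(result.mean_accuracy)                          # e.g. 0.60
```

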