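"""Classification schemes, leave-one-run-out CV, and group-level inference.

Two binary-classification arrangements probe the two feedback components in
the occluded-region voxels:

* contextual — train and test on "same object, different room" pairs: the two
  classes share the retrieved object and differ only in the visible room, so
  only contextual (room) feedback can separate them.  One problem per object
  and trial type (each object has two rooms per type → 4 problems).

* mnemonic cross-classification — train on "different object, different room"
  pairs, then test on each object's *other* room.  Room information learned
  at training cannot transfer (test rooms are disjoint), so above-chance
  transfer requires the mnemonic object signal.  Six object pairs × two
  room-assignment directions → 12 problems per trial type.

Subject-level accuracy is the unweighted mean over problems and folds
(fourfold leave-one-run-out, linear SVM with C = 1).  Group-level inference
follows the two-step scheme: per subject, a null distribution from label
permutations within run (default 100); at the group level, accuracies are
resampled with replacement from each subject's null and averaged (default
1,000 draws), and the observed group mean is compared against this null.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._svm import svm_train_decision
from .design import StimulusSet, SubjectPatterns
from .exceptions import ConfigError, DataError

Cell = tuple[str, str]  # (room, object)


@dataclass(frozen=True)
class SchemeSpec:
    """One binary problem: (room, object) cells per class, for train and test."""

    kind: str  # "contextual" | "mnemonic_crossclass"
    trial_type: str  # "episodic" | "semantic"
    train_a: tuple[Cell, ...]
    train_b: tuple[Cell, ...]
    test_a: tuple[Cell, ...]
    test_b: tuple[Cell, ...]
    fold_plan: tuple[tuple[tuple[int, ...], int], ...] | None = None  # (train runs, test run)

    def __post_init__(self) -> None:
        if self.kind == "contextual":
            if set(self.train_a) != set(self.test_a) or set(self.train_b) != set(self.test_b):
                raise ConfigError("contextual scheme requires identical train and test cells")
        elif self.kind == "mnemonic_crossclass":
            train_rooms = {r for r, _ in self.train_a + self.train_b}
            test_rooms = {r for r, _ in self.test_a + self.test_b}
            if train_rooms & test_rooms:
                raise ConfigError("mnemonic cross-classification requires disjoint train/test rooms")
        else:
            raise ConfigError(f"unknown scheme kind {self.kind!r}")


@dataclass
class ClassifierConfig:
    """Linear max-margin classifier settings (fixed regularization, C = 1)."""

    C: float = 1.0
    zscore: bool = False  # per-fold z-scoring using training statistics


@dataclass
class ClassificationResult:
    """Fold-level accuracies (averaged over binary problems) and their mean."""

    kind: str
    trial_type: str
    fold_accuracies: np.ndarray
    n_train: list[int]
    n_test: list[int]
    n_problems: int

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))


def build_contextual_scheme(stim: StimulusSet, trial_type: str) -> list[SchemeSpec]:
    """One problem per object: its two rooms (within trial type) are the classes."""
    problems = []
    for obj in stim.objects:
        rooms = stim.rooms_of(obj, trial_type)
        if len(rooms) != 2:
            raise ConfigError(f"object {obj!r} has {len(rooms)} rooms of type {trial_type}, need 2")
        a, b = ((rooms[0], obj),), ((rooms[1], obj),)
        problems.append(SchemeSpec("contextual", trial_type, a, b, a, b))
    return problems


def build_mnemonic_scheme(stim: StimulusSet, trial_type: str) -> list[SchemeSpec]:
    """Cross-classification problems: per object pair, train on one room each,
    test on the other; both room-assignment directions are emitted."""
    problems = []
    objs = list(stim.objects)
    for i in range(len(objs)):
        for j in range(i + 1, len(objs)):
            o1, o2 = objs[i], objs[j]
            r1 = stim.rooms_of(o1, trial_type)
            r2 = stim.rooms_of(o2, trial_type)
            if len(r1) != 2 or len(r2) != 2:
                raise ConfigError(f"objects need exactly 2 rooms of type {trial_type}")
            for direction in (0, 1):
                train_a = ((r1[direction], o1),)
                train_b = ((r2[direction], o2),)
                test_a = ((r1[1 - direction], o1),)
                test_b = ((r2[1 - direction], o2),)
                problems.append(
                    SchemeSpec("mnemonic_crossclass", trial_type, train_a, train_b, test_a, test_b)
                )
    return problems


@dataclass
class _ProblemData:
    """Trial bookkeeping for one binary problem on one subject's patterns."""

    idx: np.ndarray        # indices into the pattern matrix
    run: np.ndarray
    label: np.ndarray      # 0 = class A, 1 = class B
    is_train: np.ndarray   # trial belongs to the train cells
    is_test: np.ndarray
    gram: np.ndarray | None = None


def _collect(patterns: SubjectPatterns, scheme: SchemeSpec, precompute_gram: bool) -> _ProblemData:
    tt = patterns.trial_table
    cells = list(zip(tt["room"], tt["object"]))
    train_a, train_b = set(scheme.train_a), set(scheme.train_b)
    test_a, test_b = set(scheme.test_a), set(scheme.test_b)
    all_a, all_b = train_a | test_a, train_b | test_b
    sel, labels, is_train, is_test = [], [], [], []
    for i, cell in enumerate(cells):
        in_a, in_b = cell in all_a, cell in all_b
        if not (in_a or in_b):
            continue
        sel.append(i)
        labels.append(1 if in_b else 0)
        is_train.append(cell in train_a or cell in train_b)
        is_test.append(cell in test_a or cell in test_b)
    idx = np.array(sel, dtype=int)
    data = _ProblemData(
        idx=idx,
        run=tt["run"].to_numpy()[idx],
        label=np.array(labels, dtype=int),
        is_train=np.array(is_train, dtype=bool),
        is_test=np.array(is_test, dtype=bool),
    )
    if precompute_gram:
        x = patterns.data[idx]
        data.gram = x @ x.T
    return data


def _fold_plan(runs: np.ndarray, scheme: SchemeSpec) -> list[tuple[np.ndarray, int]]:
    uniq = np.unique(runs)
    if scheme.fold_plan is not None:
        return [(np.array(tr), te) for tr, te in scheme.fold_plan]
    if len(uniq) < 2:
        raise DataError("leave-one-run-out CV needs at least 2 runs")
    return [(uniq[uniq != r], int(r)) for r in uniq]


def _problem_fold_accuracy(
    pdat: _ProblemData,
    patterns: SubjectPatterns,
    scheme: SchemeSpec,
    labels: np.ndarray,
    config: ClassifierConfig,
) -> tuple[np.ndarray, list[int], list[int]]:
    folds = _fold_plan(pdat.run, scheme)
    accs, n_train, n_test = [], [], []
    for train_runs, test_run in folds:
        tr = pdat.is_train & np.isin(pdat.run, train_runs)
        te = pdat.is_test & (pdat.run == test_run)
        for mask, role in ((tr, "train"), (te, "test")):
            y = labels[mask]
            if len(np.unique(y)) < 2:
                raise DataError(
                    f"empty or single-class {role} set in fold with test run {test_run} "
                    f"({scheme.kind}/{scheme.trial_type})"
                )
        if pdat.gram is not None and not config.zscore:
            decision = svm_train_decision(
                pdat.gram[np.ix_(tr, tr)], labels[tr], pdat.gram[np.ix_(te, tr)], C=config.C
            )
        else:
            x_tr = patterns.data[pdat.idx[tr]]
            x_te = patterns.data[pdat.idx[te]]
            if config.zscore:
                mu, sd = x_tr.mean(axis=0), x_tr.std(axis=0)
                sd[sd == 0] = 1.0
                x_tr, x_te = (x_tr - mu) / sd, (x_te - mu) / sd
            decision = svm_train_decision(x_tr @ x_tr.T, labels[tr], x_te @ x_tr.T, C=config.C)
        pred = (decision > 0).astype(int)
        accs.append(float(np.mean(pred == labels[te])))
        n_train.append(int(tr.sum()))
        n_test.append(int(te.sum()))
    return np.array(accs), n_train, n_test


def run_loro_cv(
    patterns: SubjectPatterns,
    schemes: SchemeSpec | Sequence[SchemeSpec],
    config: ClassifierConfig | None = None,
) -> ClassificationResult:
    """Leave-one-run-out CV accuracy, unweighted-averaged over binary problems.

    Deterministic given inputs and config (the linear SVM dual problem for
    these small balanced folds has a unique solution).
    """
    if isinstance(schemes, SchemeSpec):
        schemes = [schemes]
    if not schemes:
        raise ConfigError("no schemes given")
    config = config or ClassifierConfig()
    per_problem = []
    n_train = n_test = None
    for scheme in schemes:
        pdat = _collect(patterns, scheme, precompute_gram=not config.zscore)
        accs, ntr, nte = _problem_fold_accuracy(pdat, patterns, scheme, pdat.label, config)
        per_problem.append(accs)
        n_train, n_test = ntr, nte
    fold_acc = np.mean(per_problem, axis=0)
    return ClassificationResult(
        kind=schemes[0].kind,
        trial_type=schemes[0].trial_type,
        fold_accuracies=fold_acc,
        n_train=n_train,
        n_test=n_test,
        n_problems=len(schemes),
    )


def permutation_null(
    patterns: SubjectPatterns,
    schemes: SchemeSpec | Sequence[SchemeSpec],
    n_perm: int = 100,
    seed: int = 0,
    config: ClassifierConfig | None = None,
) -> np.ndarray:
    """Null distribution of mean accuracies from within-run label permutations.

    Labels are shuffled within run (and within train/test role for
    cross-classification schemes) to respect exchangeability under run-wise
    CV; the full LORO-CV is recomputed per permutation.
    """
    if n_perm < 1:
        raise ConfigError("n_perm must be >= 1")
    if isinstance(schemes, SchemeSpec):
        schemes = [schemes]
    config = config or ClassifierConfig()
    rng = np.random.default_rng(seed)
    collected = [(s, _collect(patterns, s, precompute_gram=not config.zscore)) for s in schemes]
    null = np.empty(n_perm)
    for p in range(n_perm):
        per_problem = []
        for scheme, pdat in collected:
            labels = pdat.label.copy()
            for run in np.unique(pdat.run):
                for role in (pdat.is_train, pdat.is_test & ~pdat.is_train):
                    sub = np.where(role & (pdat.run == run))[0]
                    if len(sub):
                        labels[sub] = labels[rng.permutation(sub)]
            accs, _, _ = _problem_fold_accuracy(pdat, patterns, scheme, labels, config)
            per_problem.append(np.mean(accs))
        null[p] = float(np.mean(per_problem))
    return null


def group_bootstrap_test(
    per_subject_nulls: Sequence[np.ndarray],
    observed_group_mean: float,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Two-step group-level test: bootstrap a null of group-mean accuracies.

    Each bootstrap iterate draws one accuracy (with replacement) from every
    subject's permutation null and averages; p is the proportion of null
    group means ≥ the observed mean.  The headline significance rule is
    observed > 99.9th percentile of the null (see `bootstrap_significant`).
    """
    if not per_subject_nulls:
        raise DataError("no subjects")
    if n_boot < 1:
        raise ConfigError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    draws = np.column_stack([
        np.asarray(null)[rng.integers(0, len(null), size=n_boot)] for null in per_subject_nulls
    ])
    null_means = draws.mean(axis=1)
    p = float(np.mean(null_means >= observed_group_mean))
    return null_means, p


def bootstrap_significant(
    null_means: np.ndarray, observed_group_mean: float, percentile: float = 99.9
) -> bool:
    """Significance rule: observed group mean exceeds the given null percentile."""
    return bool(observed_group_mean > np.percentile(null_means, percentile))


def group_ttest(accuracies: Sequence[float], chance: float = 0.5) -> tuple[float, float]:
    """One-sided one-sample t test of subject accuracies against chance."""
    from scipy import stats

    res = stats.ttest_1samp(np.asarray(accuracies, dtype=float), chance, alternative="greater")
    return float(res.statistic), float(res.pvalue)
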