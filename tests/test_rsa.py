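"""RDM computation, model RDMs, Spearman model fits, Wilcoxon inference."""

from itertools import product

import numpy as np
import pandas as pd
import pytest

import visfeedback as vf
from visfeedback.exceptions import DataError
from visfeedback.rsa import RDM, wilcoxon_vs_zero


def _patterns_from_matrix(data, table):
    return vf.SubjectPatterns("s", "g", "V1", np.asarray(data, float),
                              table.reset_index(drop=True))


class TestCrossnobis:
    def test_noiseless_identity_cov_equals_scaled_euclidean(self, stim, small_occlusion):
        truth = vf.GroundTruthParams(n_voxels=20, w_ctx=1.0, w_mne_epi=0.4, w_mne_sem=0.2,
                                     noise_sd=0.0)
        sp = vf.simulate_subject_patterns(truth, small_occlusion, seed=0)
        rdm = vf.crossnobis_rdm(sp, noise_cov="identity", mode="conditions")
        rooms = rdm.labels["room"].tolist()
        room_mean = {r: sp.data[(sp.trial_table["room"] == r).to_numpy()].mean(axis=0)
                     for r in rooms}
        for i, j in product(range(len(rooms)), repeat=2):
            expect = np.sum((room_mean[rooms[i]] - room_mean[rooms[j]]) ** 2) / sp.n_voxels
            assert rdm.values[i, j] == pytest.approx(expect, abs=1e-10)

    def test_symmetric_with_negative_entries_under_noise(self, noise_truth, small_occlusion):
        sp = vf.simulate_subject_patterns(noise_truth, small_occlusion, seed=4)
        rdm = vf.crossnobis_rdm(sp)
        assert np.allclose(rdm.values, rdm.values.T)
        off = rdm.values[np.triu_indices_from(rdm.values, k=1)]
        assert (off < 0).any()

    def test_trial_mode_spans_one_run(self, mixed_truth, occlusion):
        sp = vf.simulate_subject_patterns(mixed_truth, occlusion, seed=0)
        rdm = vf.crossnobis_rdm(sp)
        assert rdm.values.shape == (96, 96)
        # same-room off-diagonal pairs use the same condition estimate → exactly 0
        room = rdm.labels["room"].to_numpy()
        same = (room[:, None] == room[None, :]) & ~np.eye(96, dtype=bool)
        assert np.allclose(rdm.values[same], 0.0)

    def test_unbiased_mean_near_zero_for_equal_patterns(self, stim, small_occlusion):
        # all rooms share the same true pattern (zero) → expectation of each distance is 0
        dists = []
        truth = vf.GroundTruthParams(n_voxels=12, w_ctx=0, w_mne_epi=0, w_mne_sem=0,
                                     noise_sd=1.0, orthogonalize=False)
        for seed in range(100):
            sp = vf.simulate_subject_patterns(truth, small_occlusion, seed=seed)
            rdm = vf.crossnobis_rdm(sp, noise_cov="shrinkage", mode="conditions")
            dists.append(rdm.values[np.triu_indices_from(rdm.values, k=1)].mean())
        se = np.std(dists, ddof=1) / np.sqrt(len(dists))
        assert abs(np.mean(dists)) < 4 * se + 1e-3

    def test_single_run_rejected(self, stim, mixed_truth):
        sched = vf.make_occlusion_schedule(stim, n_runs=1, reps=2, seed=0)
        sp = vf.simulate_subject_patterns(mixed_truth, sched, seed=0)
        with pytest.raises(DataError):
            vf.crossnobis_rdm(sp)


class TestPearsonRdm:
    def test_hand_computed_distances(self, stim):
        table = pd.DataFrame(
            {"run": 1, "trial_index": range(3), "onset_s": [0.0, 2.5, 5.0], "duration_s": 1.5,
             "room": ["r1", "r2", "r3"], "object": ["a", "a", "b"],
             "trial_type": "episodic", "phase": "sensory"}
        )
        rows = np.array([[1.0, 2.0, 3.0, 4.0],
                         [2.0, 4.0, 6.0, 8.0],     # perfectly correlated with row 0
                         [4.0, 3.0, 2.0, 1.0]])    # perfectly anticorrelated
        rdm = vf.pearson_rdm(_patterns_from_matrix(rows, table))
        assert rdm.values[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert rdm.values[0, 2] == pytest.approx(2.0, abs=1e-12)
        # hand-computed: r([1,2,3,4],[2,4,6,8]) = 1 → d = 0; vs reversed → −1 → d = 2
        r02 = np.corrcoef(rows[1], rows[2])[0, 1]
        assert rdm.values[1, 2] == pytest.approx(1 - r02, abs=1e-12)

    def test_zero_variance_row_rejected(self, stim):
        table = pd.DataFrame(
            {"run": 1, "trial_index": [0, 1], "onset_s": [0.0, 2.0], "duration_s": 1.0,
             "room": ["r1", "r2"], "object": ["a", "b"], "trial_type": "episodic",
             "phase": "sensory"}
        )
        with pytest.raises(DataError, match="zero-variance"):
            vf.pearson_rdm(_patterns_from_matrix([[1.0, 1.0, 1.0], [0.0, 1.0, 2.0]], table))


def _toy_labels(reps=2):
    """2 objects × 2 rooms each, `reps` repetitions, all episodic."""
    rows = []
    for rep in range(reps):
        for room, obj in [("rA", "tv"), ("rB", "tv"), ("rC", "bed"), ("rD", "bed")]:
            rows.append({"room": room, "object": obj, "trial_type": "episodic", "run": 1})
    return pd.DataFrame(rows)


class TestModelRdm:
    def test_full_design_span(self, occlusion):
        labels = occlusion[occlusion["run"] == 1].reset_index(drop=True)
        model = vf.build_model_rdm(labels, "contextual")
        assert model.values.shape == (96, 96)

    def test_contextual_same_room_is_zero(self):
        labels = _toy_labels()
        model = vf.build_model_rdm(labels, "contextual")
        room = labels["room"].to_numpy()
        same = room[:, None] == room[None, :]
        assert np.all(model.values[same] == 0)
        assert np.all(model.values[~same] == 1)
        # same-room off-diagonal cells stay included in the contextual model
        assert model.include[0, 4]

    def test_mnemonic_values_and_exclusions(self):
        labels = _toy_labels(reps=2)
        model = vf.build_model_rdm(labels, "mnemonic")
        room = labels["room"].to_numpy()
        obj = labels["object"].to_numpy()
        same_room = room[:, None] == room[None, :]
        same_obj = obj[:, None] == obj[None, :]
        assert np.all(model.values[same_obj & ~same_room] == 0)
        assert np.all(model.values[~same_obj] == 1)
        assert not model.include[same_room].any()
        # excluded off-diagonal count = Σ_rooms reps·(reps−1)
        n_excl = (~model.include & ~np.eye(8, dtype=bool) & same_room).sum()
        assert n_excl == 4 * 2 * 1

    def test_trial_type_restriction_masks_other_type(self, occlusion):
        labels = occlusion[occlusion["run"] == 1].reset_index(drop=True)
        model = vf.build_model_rdm(labels, "contextual", trial_type="episodic")
        sem = (labels["trial_type"] == "semantic").to_numpy()
        assert not model.include[sem].any()
        assert not model.include[:, sem].any()


def _rank_with_ties(values):
    """Independent average-rank implementation for the oracle."""
    values = np.asarray(values, float)
    ranks = np.empty(len(values))
    order = np.argsort(values, kind="stable")
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


class TestFitModel:
    def _toy_rdm(self, values, reps=2):
        labels = _toy_labels(reps=reps)
        return RDM(np.asarray(values, float), labels, "crossnobis")

    def test_perfect_and_inverted_fit(self):
        labels = _toy_labels(reps=2)
        model = vf.build_model_rdm(labels, "contextual")
        fit = vf.fit_model(self._toy_rdm(model.values), model)
        assert fit.rho == pytest.approx(1.0)
        assert np.isfinite(fit.z)
        fit_neg = vf.fit_model(self._toy_rdm(-model.values), model)
        assert fit_neg.rho == pytest.approx(-1.0)

    def test_ties_match_hand_ranked_pearson(self):
        labels = _toy_labels(reps=1)
        model = vf.build_model_rdm(labels, "mnemonic")
        rng = np.random.default_rng(0)
        neural = rng.choice([0.1, 0.2, 0.2, 0.5], size=(4, 4))
        neural = (neural + neural.T) / 2
        np.fill_diagonal(neural, 0)
        fit = vf.fit_model(RDM(neural, labels, "crossnobis"), model)
        triu = np.triu(np.ones((4, 4), bool), 1)
        cells = model.include & triu
        rx = _rank_with_ties(neural[cells])
        ry = _rank_with_ties(model.values[cells])
        expect = np.corrcoef(rx, ry)[0, 1]
        assert fit.rho == pytest.approx(expect, abs=1e-12)

    def test_invariance_to_monotone_transform(self, mixed_truth, small_occlusion):
        sp = vf.simulate_subject_patterns(mixed_truth, small_occlusion, seed=1)
        rdm = vf.crossnobis_rdm(sp)
        model = vf.build_model_rdm(rdm.labels, "contextual")
        fit1 = vf.fit_model(rdm, model)
        cubed = RDM(rdm.values ** 3, rdm.labels, rdm.metric)
        fit2 = vf.fit_model(cubed, model)
        assert fit1.rho == pytest.approx(fit2.rho, abs=1e-12)


class TestWilcoxon:
    def test_exact_one_sided_smallest_p(self):
        stat, p = wilcoxon_vs_zero(np.array([1.0, 2, 3, 4, 5]), alternative="greater")
        assert p == pytest.approx(1 / 32)

    def test_symmetric_two_sided_p_one(self):
        stat, p = wilcoxon_vs_zero(np.array([-2.0, 2.0]), alternative="two-sided")
        assert p == pytest.approx(1.0)

    def test_matches_full_enumeration_n6(self):
        values = np.array([0.8, -0.3, 1.9, 0.45, -1.2, 2.6])
        _, p = wilcoxon_vs_zero(values, alternative="greater")
        # brute-force oracle: all 2^6 sign assignments of |values| ranks
        ranks = _rank_with_ties(np.abs(values))
        w_obs = ranks[values > 0].sum()
        count = 0
        for signs in product([0, 1], repeat=6):
            w = ranks[np.array(signs, bool)].sum()
            count += w >= w_obs
        assert p == pytest.approx(count / 64)

    def test_all_zero_rejected(self):
        with pytest.raises(DataError):
            wilcoxon_vs_zero(np.zeros(4))
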