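"""Differentiation index, outlier flagging, and feedforward–feedback coupling."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import visfeedback as vf
from visfeedback.differentiation import (
    OUTLIER_SD,
    bh_adjust,
    ff_fb_correlation,
    spearman_test,
    zscore_and_flag_outliers,
)
from visfeedback.exceptions import DataError
from visfeedback.rsa import RDM


def _rdm_from(values, rooms, objects):
    labels = pd.DataFrame({"room": rooms, "object": objects,
                           "trial_type": "episodic", "run": 1})
    return RDM(np.asarray(values, float), labels, "crossnobis")


class TestDifferentiationIndex:
    def test_hand_computed_toy(self):
        # two objects, two trials each; within = {0.2, 0.4}, between = {1.0, 1.2, 0.8, 1.0}
        values = np.array([
            [0.0, 0.2, 1.0, 1.2],
            [0.2, 0.0, 0.8, 1.0],
            [1.0, 0.8, 0.0, 0.4],
            [1.2, 1.0, 0.4, 0.0],
        ])
        rdm = _rdm_from(values, ["r1", "r2", "r3", "r4"], ["tv", "tv", "bed", "bed"])
        di = vf.differentiation_index(rdm)
        assert di == pytest.approx(1.0 - 0.3)

    def test_constant_dissimilarities_give_zero(self):
        values = np.full((4, 4), 0.7)
        np.fill_diagonal(values, 0)
        rdm = _rdm_from(values, ["r1", "r2", "r3", "r4"], ["tv", "tv", "bed", "bed"])
        assert vf.differentiation_index(rdm) == pytest.approx(0.0)

    def test_antisymmetric_under_within_between_swap(self):
        # oracle: di computed from explicit pair masks; swapping the two pair
        # sets in the formula flips the sign exactly
        rng = np.random.default_rng(1)
        values = rng.random((4, 4))
        values = (values + values.T) / 2
        np.fill_diagonal(values, 0)
        rdm = _rdm_from(values, ["r1", "r2", "r3", "r4"], ["tv", "tv", "bed", "bed"])
        within = values[np.array([[0, 1], [2, 3]])[:, 0], np.array([[0, 1], [2, 3]])[:, 1]]
        between = values[np.triu_indices(4, 1)]
        between = np.array([values[0, 2], values[0, 3], values[1, 2], values[1, 3]])
        di = vf.differentiation_index(rdm)
        assert di == pytest.approx(between.mean() - within.mean())
        assert -(within.mean() - between.mean()) == pytest.approx(di)
        # sign flips when between and within structure is inverted in the data
        hi = np.array([[0, 2, .1, .1], [2, 0, .1, .1], [.1, .1, 0, 2], [.1, .1, 2, 0]])
        r1 = _rdm_from(hi, ["r1", "r2", "r3", "r4"], ["tv", "tv", "bed", "bed"])
        r2 = _rdm_from(hi, ["r1", "r2", "r3", "r4"], ["tv", "bed", "tv", "bed"])
        assert vf.differentiation_index(r1) < 0 < vf.differentiation_index(r2)

    def test_same_room_pairs_excluded_by_default_policy(self, mixed_truth, occlusion):
        sp = vf.simulate_subject_patterns(mixed_truth, occlusion, seed=0)
        rdm = vf.crossnobis_rdm(sp)
        # default policy must differ from include_all: same-room cells are all 0
        di_excl = vf.differentiation_index(rdm, trial_type="episodic")
        di_all = vf.differentiation_index(rdm, trial_type="episodic", pair_policy="include_all")
        assert di_excl != pytest.approx(di_all)

    def test_feedforward_single_record_per_subject(self, mixed_truth, sensory):
        sp = vf.simulate_subject_patterns(mixed_truth, sensory, seed=0)
        rdm = vf.pearson_rdm(sp)
        di = vf.differentiation_index(rdm)  # no trial-type split
        assert np.isfinite(di)


class TestOutlierRule:
    def test_tail_mass_beyond_threshold(self):
        tail = 2 * (1 - stats.norm.cdf(OUTLIER_SD))
        assert f"{tail:.2g}" == "0.001"

    def test_identical_values_no_outliers(self):
        df = pd.DataFrame({"subject": [f"s{i}" for i in range(4)], "group": "g",
                           "roi": "V1", "trial_type": "episodic", "pathway": "feedback",
                           "di": 1.0, "z_di": np.nan, "outlier": False})
        out = zscore_and_flag_outliers(df)
        assert (out["z_di"] == 0).all()
        assert not out["outlier"].any()

    def test_single_gross_outlier_flagged(self):
        rng = np.random.default_rng(0)
        dis = np.concatenate([rng.standard_normal(100), [10.0]])
        df = pd.DataFrame({"subject": [f"s{i}" for i in range(101)], "group": "g",
                           "roi": "V1", "trial_type": "episodic", "pathway": "feedback",
                           "di": dis, "z_di": np.nan, "outlier": False})
        out = zscore_and_flag_outliers(df)
        assert out["outlier"].sum() == 1
        assert out.loc[out["outlier"], "di"].iloc[0] == 10.0


class TestSpearman:
    def test_monotone_transform_gives_rho_one(self):
        x = np.array([0.2, 1.5, 0.9, 2.4, 3.0])
        rho, p = spearman_test(x, np.exp(x), alternative="greater")
        assert rho == pytest.approx(1.0)

    def test_exact_p_matches_enumeration_n4(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.2, 3.4, 2.2, 4.8])
        rho, p = spearman_test(x, y, alternative="greater")
        # oracle: brute force over all 24 pairings
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        obs = np.corrcoef(rx, ry)[0, 1]
        count = total = 0
        for perm in permutations(ry):
            total += 1
            count += np.corrcoef(rx, perm)[0, 1] >= obs - 1e-12
        assert p == pytest.approx(count / total)

    def test_independent_values_rho_near_zero(self):
        rng = np.random.default_rng(3)
        rhos = [spearman_test(rng.standard_normal(12), rng.standard_normal(12))[0]
                for _ in range(200)]
        se = 1 / np.sqrt(11)  # var(rho) ≈ 1/(n−1)
        assert abs(np.mean(rhos)) < 2 * se / np.sqrt(200)


class TestFfFbCorrelation:
    def _table(self, ff, fb, group="g", roi="V1"):
        rows = []
        for i, (f, b) in enumerate(zip(ff, fb)):
            rows.append({"subject": f"s{i}", "group": group, "roi": roi, "trial_type": "all",
                         "pathway": "feedforward", "di": f, "z_di": 0.0, "outlier": False})
            rows.append({"subject": f"s{i}", "group": group, "roi": roi,
                         "trial_type": "episodic", "pathway": "feedback", "di": b,
                         "z_di": 0.0, "outlier": False})
        return pd.DataFrame(rows)

    def test_monotone_coupling_recovered(self):
        ff = np.arange(8, dtype=float)
        out = ff_fb_correlation(self._table(ff, ff ** 3))
        assert out["rho"].iloc[0] == pytest.approx(1.0)

    def test_outliers_excluded_from_pairs(self):
        ff = np.arange(8, dtype=float)
        table = self._table(ff, ff + 0.5)
        table.loc[0, "outlier"] = True  # drop subject 0's feedforward record
        out = ff_fb_correlation(table)
        assert out["n"].iloc[0] == 7

    def test_too_few_pairs_rejected(self):
        with pytest.raises(DataError):
            ff_fb_correlation(self._table([1.0, 2.0], [1.0, 2.0]))


class TestBhAdjust:
    def test_hand_stepup_example(self):
        adj = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged_and_monotone(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)
        rng = np.random.default_rng(0)
        p = rng.random(50)
        adj = bh_adjust(p)
        assert np.all(adj >= p - 1e-15)

    def test_matches_brute_force_stepup(self):
        def brute(p):
            p = np.asarray(p, float)
            m = len(p)
            order = np.argsort(p)
            adj = np.empty(m)
            running = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                running = min(running, p[i] * m / rank)
                adj[i] = running
            return adj

        rng = np.random.default_rng(42)
        for _ in range(200):
            p = rng.random(rng.integers(1, 12))
            assert np.allclose(bh_adjust(p), brute(p))
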