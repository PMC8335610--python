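"""Comparison harness and annotation agreement."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from sklearn.metrics import cohen_kappa_score

from anstages.stats import (
    DEFAULT_PAIRS, cohen_kappa, compare_table, comparison_frame,
    consensus_label, kruskal_wallis, light_kappa, mann_whitney,
    proportion_ztest, significance_tier,
)


class TestKruskalWallis:
    def test_identical_groups_h_zero(self):
        h, p = kruskal_wallis([[1, 2, 3], [1, 2, 3]])
        assert h == pytest.approx(0.0, abs=1e-12)

    def test_all_constant_degenerate(self):
        assert kruskal_wallis([[5, 5], [5, 5, 5]]) == (0.0, 1.0)

    def test_hand_ranked_formula(self):
        """Two groups [1,2,3] vs [4,5,6]: ranks 1..6, no ties.
        H = 12/(N(N+1)) * sum(R_g^2/n_g) - 3(N+1) = 12/42*(36/3+225/3)-21."""
        expected = 12 / 42 * (6 ** 2 / 3 + 15 ** 2 / 3) - 21
        h, _ = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert h == pytest.approx(expected, abs=1e-12)

    def test_reference_agreement_on_fuzz(self, rng):
        for _ in range(20):
            gs = [rng.normal(size=rng.integers(5, 15)).round(1) for _ in range(3)]
            h, p = kruskal_wallis(gs)
            ref_h, ref_p = sps.kruskal(*gs)
            assert h == pytest.approx(ref_h, abs=1e-8)
            assert p == pytest.approx(ref_p, abs=1e-8)

    def test_missing_dropped(self):
        h1, _ = kruskal_wallis([[1, 2, math.nan], [3, 4]])
        h2, _ = kruskal_wallis([[1, 2], [3, 4]])
        assert h1 == h2


class TestMannWhitney:
    def test_identical_samples_p_high(self):
        _, p = mann_whitney([1, 2, 3, 4], [1, 2, 3, 4])
        assert p >= 0.99

    def test_exact_enumeration_small_sample(self):
        u, p = mann_whitney([1, 2], [3, 4])
        assert u == 0.0
        assert p == pytest.approx(1 / 3)

    def test_symmetric(self, rng):
        a, b = rng.normal(size=12), rng.normal(1, 1, size=9)
        assert mann_whitney(a, b)[1] == pytest.approx(mann_whitney(b, a)[1])

    def test_exact_matches_scipy_exact_no_ties(self, rng):
        for _ in range(10):
            a = rng.permutation(20)[:6].astype(float)
            b = rng.permutation(40)[20:27].astype(float) + 0.5
            _, p = mann_whitney(a, b)
            ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_empty_sample_error(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    def test_type_one_error_calibrated(self, rng):
        """Null rejection rate at alpha=.05 stays within 5% +/- 1.5% over
        2,000 same-distribution simulations (n=30/group)."""
        rejections = 0
        sims = 2000
        for _ in range(sims):
            a = rng.normal(size=30)
            b = rng.normal(size=30)
            if mann_whitney(a, b)[1] < 0.05:
                rejections += 1
        assert abs(rejections / sims - 0.05) < 0.015


class TestProportionZ:
    def test_equal_proportions(self):
        z, p = proportion_ztest(5, 10, 50, 100)
        assert z == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(1.0)

    def test_z_squared_equals_chisquare(self, rng):
        for _ in range(100):
            n_a, n_b = rng.integers(5, 80, size=2)
            s_a, s_b = rng.integers(1, n_a), rng.integers(1, n_b)
            z, _ = proportion_ztest(int(s_a), int(n_a), int(s_b), int(n_b))
            table = [[s_a, n_a - s_a], [s_b, n_b - s_b]]
            chi2 = sps.chi2_contingency(table, correction=False).statistic
            assert z ** 2 == pytest.approx(chi2, abs=1e-9)

    def test_degenerate_flagged(self):
        z, p = proportion_ztest(0, 10, 0, 10)
        assert math.isnan(z) and p == 1.0


class TestCompareTable:
    def _table(self, rng, shift=0.0):
        n = 30
        groups, rows = {}, {}
        for g in ("AN", "treatment", "recovered", "focused_control",
                  "random_control"):
            for i in range(n):
                uid = f"{g}{i}"
                groups[uid] = g
                rows[uid] = {
                    "flat": rng.normal(),
                    "shifted": rng.normal() + (shift if g == "AN" else 0.0),
                    "flag": bool(rng.random() < (0.8 if g == "AN" else 0.2)),
                }
        return pd.DataFrame.from_dict(rows, orient="index"), pd.Series(groups)

    def test_identical_feature_fails_screen(self, rng):
        ft, groups = self._table(rng)
        ft["const"] = 1.0
        rows = {r.feature: r for r in
                compare_table(ft, groups, boolean_columns=["flag"])}
        assert rows["const"].pair_p == {}
        assert rows["const"].kw_p == 1.0

    def test_large_shift_all_an_pairs_significant(self, rng):
        ft, groups = self._table(rng, shift=3.0)
        ft = ft[["shifted"]]
        row = compare_table(ft, groups)[0]
        for pair in DEFAULT_PAIRS:
            if "AN" in pair:
                assert row.pair_tier[pair] == "<.001"

    def test_row_count_and_frame_layout(self, rng):
        ft, groups = self._table(rng)
        rows = compare_table(ft, groups, boolean_columns=["flag"])
        assert len(rows) == ft.shape[1]
        frame = comparison_frame(rows)
        assert "median_AN" in frame.columns

    def test_boolean_uses_ratios(self, rng):
        ft, groups = self._table(rng)
        rows = {r.feature: r for r in
                compare_table(ft, groups, boolean_columns=["flag"])}
        assert 0 <= rows["flag"].group_stats["AN"] <= 1
        assert rows["flag"].pair_p[("AN", "treatment")] < 0.05

    def test_unknown_group_error(self, rng):
        ft, groups = self._table(rng)
        with pytest.raises(ValueError):
            compare_table(ft, groups, pairs=[("AN", "nope")])

    def test_permutation_equivariant_in_group_order(self, rng):
        ft, groups = self._table(rng, shift=1.0)
        rows1 = compare_table(ft, groups, boolean_columns=["flag"])
        shuffled = groups.sample(frac=1, random_state=1)
        rows2 = compare_table(ft, shuffled, boolean_columns=["flag"])
        for r1, r2 in zip(rows1, rows2):
            assert r1.group_stats == pytest.approx(r2.group_stats, nan_ok=True)
            for pair in r1.pair_p:
                assert r1.pair_p[pair] == pytest.approx(r2.pair_p[pair],
                                                        nan_ok=True)


@pytest.mark.parametrize("p, tier", [(0.2, "ns"), (0.04, "<.05"),
                                     (0.009, "<.01"), (0.0005, "<.001"),
                                     (math.nan, "na")])
def test_tiers(p, tier):
    assert significance_tier(p) == tier


class TestKappa:
    def test_identical_vectors(self):
        assert cohen_kappa(list("aabb"), list("aabb")) == 1.0

    def test_hand_computed_zero(self):
        # p_o = 0.5; marginals 0.5/0.5 each -> p_e = 0.5 -> kappa = 0
        assert cohen_kappa(list("aabb"), list("abab")) == pytest.approx(0.0)

    def test_sklearn_cross_check(self, rng):
        for _ in range(20):
            a = rng.integers(0, 3, size=50)
            b = rng.integers(0, 3, size=50)
            assert cohen_kappa(a, b) == pytest.approx(
                cohen_kappa_score(a, b), abs=1e-10)

    def test_bounded_above_by_one(self, rng):
        for _ in range(50):
            a = rng.integers(0, 2, size=10)
            b = rng.integers(0, 2, size=10)
            assert cohen_kappa(a, b) <= 1.0 + 1e-12

    def test_degenerate_constant_annotators(self):
        assert cohen_kappa(["x", "x"], ["x", "x"]) == 1.0


class TestLightKappa:
    def test_two_annotators_equals_cohen(self, rng):
        m = rng.integers(0, 3, size=(40, 2))
        res = light_kappa(m)
        assert res.light_kappa == pytest.approx(cohen_kappa(m[:, 0], m[:, 1]))

    def test_perfect_agreement(self):
        m = np.tile(np.array([["a"], ["b"], ["a"]], dtype=object), (1, 5))
        assert light_kappa(m).light_kappa == 1.0

    def test_bruteforce_average_over_pairs(self, rng):
        m = rng.integers(0, 3, size=(60, 5))
        res = light_kappa(m)
        pairs = list(itertools.combinations(range(5), 2))
        assert len(res.pairwise_kappas) == 10
        expected = np.mean([cohen_kappa(m[:, i], m[:, j]) for i, j in pairs])
        assert res.light_kappa == pytest.approx(expected, abs=1e-12)


class TestConsensus:
    def test_three_agree(self):
        m = [["AN", "AN", "AN", "ctrl", "doubt"]]
        assert consensus_label(m) == ["AN"]

    def test_no_quorum_falls_back(self):
        m = [["AN", "AN", "ctrl", "ctrl", "doubt"]]
        assert consensus_label(m) == ["doubtful"]

    def test_exhaustive_over_all_vote_patterns(self):
        """All 3^5 patterns against an explicit counting oracle."""
        labels = ["a", "b", "c"]
        patterns = list(itertools.product(labels, repeat=5))
        ours = consensus_label(list(patterns))
        for pat, got in zip(patterns, ours):
            counts = {lab: pat.count(lab) for lab in labels}
            winners = [lab for lab, c in counts.items() if c >= 3]
            assert got == (winners[0] if winners else "doubtful")

    def test_too_few_annotators_error(self):
        with pytest.raises(ValueError):
            consensus_label([["a", "a"]], min_agree=3)
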