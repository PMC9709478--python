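"""Rank tests, chi-square, burden and fold-change correlations."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from trtscreen.stats import (
    chi_square_2x2,
    compare_burden_groups,
    correlate_burden_trait,
    fc_correlation_per_pair,
    spearman,
    trt_burden,
    wilcoxon_rank_sum,
)


def enumerate_wilcoxon_p(x, y):
    """Brute-force exact two-sided p over all group assignments of the
    pooled ranks (valid without ties)."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n1 = len(x)
    w_obs = ranks[:n1].sum()
    mu = n1 * (len(pooled) + 1) / 2
    stats = [
        sum(comb) for comb in itertools.combinations(ranks, n1)
    ]
    tail = np.mean([abs(w - mu) >= abs(w_obs - mu) - 1e-9 for w in stats])
    return tail


class TestWilcoxon:
    def test_exact_minimal_p_for_three_vs_three(self):
        res = wilcoxon_rank_sum([1, 2, 3], [101, 102, 103])
        assert res.pvalue == pytest.approx(0.1)

    def test_identical_groups_give_no_evidence(self):
        res = wilcoxon_rank_sum([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert res.pvalue > 0.9

    def test_label_swap_symmetry(self):
        x, y = [3.1, 0.2, 5.5, 2.2], [4.0, 1.1, 9.9]
        assert wilcoxon_rank_sum(x, y).pvalue == pytest.approx(
            wilcoxon_rank_sum(y, x).pvalue
        )

    def test_empty_group_is_error(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])

    def test_exact_matches_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            n1, n2 = rng.integers(2, 8, size=2)
            pooled = rng.permutation(np.arange(1.0, n1 + n2 + 1))  # no ties
            x, y = pooled[:n1], pooled[n1:]
            res = wilcoxon_rank_sum(x, y, exact=True)
            assert res.pvalue == pytest.approx(enumerate_wilcoxon_p(x, y))

    def test_null_rejection_rate_near_nominal(self):
        # permuting labels on null data rejects at ~ the 5% nominal rate
        rng = np.random.default_rng(6)
        values = rng.normal(size=30)
        rejections = 0
        n_perm = 1000
        for _ in range(n_perm):
            perm = rng.permutation(values)
            p = wilcoxon_rank_sum(perm[:12], perm[12:], exact=False).pvalue
            rejections += p < 0.05
        assert abs(rejections / n_perm - 0.05) < 0.02


class TestSpearman:
    def test_monotone_coupling(self):
        assert spearman([1, 2, 3, 4, 5], [10, 20, 40, 80, 160]).statistic == pytest.approx(1.0)
        assert spearman([1, 2, 3, 4, 5], [5, 4, 3, 2, 1]).statistic == pytest.approx(-1.0)

    def test_six_point_example_matches_rank_oracle(self):
        x = [3.0, 1.0, 4.0, 1.0, 5.0, 9.0]  # tie in x -> average ranks
        y = [2.0, 7.0, 1.0, 8.0, 2.0, 8.0]
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert spearman(x, y).statistic == pytest.approx(expected)

    def test_exact_p_matches_permutation_enumeration(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [2.0, 1.0, 4.0, 3.0, 5.0]
        res = spearman(x, y)
        # independent enumeration over all 120 orderings
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        rho_obs = np.corrcoef(rx, ry)[0, 1]
        null = [
            np.corrcoef(rx, np.array(p))[0, 1]
            for p in itertools.permutations(ry)
        ]
        expected = np.mean([abs(r) >= abs(rho_obs) - 1e-12 for r in null])
        assert res.pvalue == pytest.approx(expected)

    def test_constant_input_reported_missing(self):
        res = spearman([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])
        assert math.isnan(res.statistic) and math.isnan(res.pvalue)

    def test_large_n_uses_t_approximation(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(size=40), rng.normal(size=40)
        res = spearman(x, y)
        ref = sps.spearmanr(x, y)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.pvalue == pytest.approx(ref.pvalue, rel=1e-6)


class TestChiSquare:
    def test_balanced_table_gives_zero(self):
        res = chi_square_2x2([[10, 10], [10, 10]])
        assert res.statistic == 0.0 and res.pvalue == pytest.approx(1.0)

    def test_hand_computed_statistic(self):
        # all expected counts 12.5; sum (O-E)^2/E = 4 * (7.5^2 / 12.5) = 18
        res = chi_square_2x2([[20, 5], [5, 20]])
        assert res.statistic == pytest.approx(18.0)

    def test_transpose_invariance(self):
        t = np.array([[12, 3], [7, 9]])
        assert chi_square_2x2(t).statistic == pytest.approx(chi_square_2x2(t.T).statistic)

    def test_zero_marginal_is_error(self):
        with pytest.raises(ValueError, match="marginal"):
            chi_square_2x2([[0, 0], [5, 20]])

    def test_continuity_correction_flag(self):
        t = [[20, 5], [5, 20]]
        assert chi_square_2x2(t, correction=True).statistic < chi_square_2x2(t).statistic


class TestBurden:
    def make(self, cis_rows, trans_rows, patients=("p1",)):
        cis = pd.DataFrame(cis_rows, columns=patients).astype(bool)
        trans = pd.DataFrame(trans_rows, columns=patients).astype(bool)
        return cis, trans

    def test_all_false_gives_zeros(self):
        cis, trans = self.make({"p1": [False]}, {"p1": [False]})
        cis.index, trans.index = ["a__b"], ["c__d"]
        b = trt_burden(cis, trans)
        assert (b.loc["p1"] == 0).all()

    def test_disjoint_pairs_sum_in_total(self):
        cis = pd.DataFrame({"p1": [True, True, True]}, index=["a__b", "c__d", "e__f"])
        trans = pd.DataFrame({"p1": [True, True]}, index=["g__h", "i__j"])
        b = trt_burden(cis, trans)
        assert b.loc["p1", "cis"] == 3
        assert b.loc["p1", "trans"] == 2
        assert b.loc["p1", "total"] == 5

    def test_convergent_pair_directions_counted_once(self):
        cis = pd.DataFrame({"p1": []}, dtype=bool)
        trans = pd.DataFrame({"p1": [True, True]}, index=["a__b", "b__a"])
        b = trt_burden(cis, trans)
        assert b.loc["p1", "trans"] == 2
        assert b.loc["p1", "total"] == 1

    def test_mismatched_patient_columns_rejected(self):
        cis = pd.DataFrame({"p1": [True]}, index=["a__b"])
        trans = pd.DataFrame({"p2": [True]}, index=["c__d"])
        with pytest.raises(ValueError):
            trt_burden(cis, trans)


class TestBurdenTraitOps:
    def test_compare_groups_on_separated_data(self):
        burden = pd.Series([1, 2, 3, 30, 40, 50], index=list("abcdef"))
        labels = pd.Series(["x"] * 3 + ["y"] * 3, index=list("abcdef"))
        res = compare_burden_groups(burden, labels)
        assert res.pvalue == pytest.approx(0.1)

    def test_three_level_labels_rejected(self):
        burden = pd.Series([1, 2, 3], index=list("abc"))
        labels = pd.Series(["x", "y", "z"], index=list("abc"))
        with pytest.raises(ValueError):
            compare_burden_groups(burden, labels)

    def test_correlate_requires_three_complete_pairs(self):
        burden = pd.Series([1, 2, 3], index=list("abc"))
        trait = pd.Series([1.0, np.nan, 3.0], index=list("abc"))
        with pytest.raises(ValueError):
            correlate_burden_trait(burden, trait)

    def test_missing_traits_dropped_pairwise(self):
        burden = pd.Series([1, 2, 3, 4, 5], index=list("abcde"))
        trait = pd.Series([10.0, 20.0, np.nan, 40.0, 50.0], index=list("abcde"))
        res = correlate_burden_trait(burden, trait)
        assert res.n == 4 and res.statistic == 1.0


class TestFcCorrelation:
    def diag(self, pairs):
        rows = []
        for pid, (ifc, dfc) in pairs.items():
            for i, (a, b) in enumerate(zip(ifc, dfc)):
                rows.append((pid, f"p{i}", a, b))
        return pd.DataFrame(
            rows, columns=["pair_id", "patient_id", "intergenic_fc", "downstream_fc"]
        )

    def test_perfectly_coupled_pair(self):
        d = self.diag({"a__b": ([1, 2, 3, 4, 5], [2, 4, 6, 8, 10])})
        out = fc_correlation_per_pair(d)
        assert out.loc[0, "spearman_r"] == pytest.approx(1.0)

    def test_anti_coupled_pair(self):
        d = self.diag({"a__b": ([1, 2, 3, 4, 5], [10, 8, 6, 4, 2])})
        assert fc_correlation_per_pair(d).loc[0, "spearman_r"] == pytest.approx(-1.0)

    def test_constant_or_short_vectors_reported_missing(self):
        d = self.diag(
            {
                "const": ([1, 1, 1, 1], [1, 2, 3, 4]),
                "short": ([1, np.nan, np.nan, np.nan], [1, 2, 3, 4]),
            }
        )
        out = fc_correlation_per_pair(d).set_index("pair_id")
        assert np.isnan(out.loc["const", "spearman_r"])
        assert np.isnan(out.loc["short", "spearman_r"])

    def test_nonfinite_fold_changes_dropped_pairwise(self):
        d = self.diag({"a__b": ([1, 2, np.inf, 4, 5, 6], [2, 4, 9, 8, 10, 12])})
        out = fc_correlation_per_pair(d)
        assert out.loc[0, "n"] == 5
        assert out.loc[0, "spearman_r"] == pytest.approx(1.0)
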