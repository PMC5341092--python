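"""Rank statistics and exact tests against independent oracles."""

import numpy as np
import pytest
import statsmodels.stats.multitest as smm
from hypothesis import given, settings, strategies as hst
from scipy import stats as sps

from essevo import stats as st


def exhaustive_spearman(x, y):
    """1 - 6*sum(d^2)/(n(n^2-1)) on untied data (closed-form oracle)."""
    rx = st.average_ranks(x)
    ry = st.average_ranks(y)
    n = len(x)
    return 1.0 - 6.0 * np.sum((rx - ry) ** 2) / (n * (n**2 - 1))


class TestSpearman:
    def test_hand_example(self):
        # d = (-1, 1, -1, 1): rho = 1 - 24/60 = 0.6
        res = st.spearman([1, 2, 3, 4], [2, 1, 4, 3])
        assert res.statistic == pytest.approx(0.6)
        assert res.statistic == pytest.approx(
            exhaustive_spearman([1, 2, 3, 4], [2, 1, 4, 3])
        )

    def test_perfect_monotone(self):
        x = np.array([3.0, 1.0, 10.0, 7.0])
        res = st.spearman(x, np.exp(x))
        assert res.statistic == pytest.approx(1.0)
        assert res.p_raw == 0.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_scipy(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=40)
        y = rng.normal(size=40) + 0.4 * x
        res = st.spearman(x, y)
        ref = sps.spearmanr(x, y)
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p_raw == pytest.approx(ref.pvalue, rel=1e-9)

    def test_ties_use_average_ranks(self):
        x = [1, 1, 2, 3, 3, 3]
        y = [2, 1, 5, 4, 4, 6]
        ref = sps.spearmanr(x, y)
        assert st.spearman(x, y).statistic == pytest.approx(ref.statistic)

    @given(hst.integers(min_value=0, max_value=500))
    @settings(max_examples=25, deadline=None)
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        base = st.spearman(x, y).statistic
        assert st.spearman(np.exp(x), y**3).statistic == pytest.approx(base)

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            st.spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestPartialSpearman:
    def test_no_controls_equals_spearman(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=20), rng.normal(size=20)
        assert st.partial_spearman(x, y).statistic == pytest.approx(
            st.spearman(x, y).statistic
        )

    def test_near_perfect_dependence_with_control(self):
        # y is x with jitter just large enough to break rank ties (exact
        # duplication gives a singular rank-correlation matrix, an error)
        rng = np.random.default_rng(1)
        x = rng.normal(size=30)
        y = x + 0.01 * rng.normal(size=30)
        z = rng.normal(size=(1, 30))
        res = st.partial_spearman(x, y, z)
        assert res.statistic == pytest.approx(1.0, abs=0.05)
        with pytest.raises(ValueError):
            st.partial_spearman(x, x.copy(), z)

    @pytest.mark.parametrize("seed", [3, 4, 5, 6])
    def test_matches_residual_regression_oracle(self, seed):
        # regress ranks on control ranks, correlate residuals
        rng = np.random.default_rng(seed)
        n = 8
        x = rng.normal(size=n)
        y = 0.5 * x + rng.normal(size=n)
        z = rng.normal(size=(2, n))
        mine = st.partial_spearman(x, y, z).statistic
        rx, ry = st.average_ranks(x), st.average_ranks(y)
        A = np.column_stack([np.ones(n)] + [st.average_ranks(v) for v in z])
        res_x = rx - A @ np.linalg.lstsq(A, rx, rcond=None)[0]
        res_y = ry - A @ np.linalg.lstsq(A, ry, rcond=None)[0]
        oracle = (res_x @ res_y) / np.sqrt((res_x @ res_x) * (res_y @ res_y))
        assert mine == pytest.approx(oracle, abs=1e-10)

    def test_needs_enough_observations(self):
        with pytest.raises(ValueError):
            st.partial_spearman([1, 2, 3, 4], [4, 3, 2, 1], np.zeros((2, 4)) + [[1, 2, 3, 4]])


class TestKruskalWallis:
    def test_hand_example(self):
        assert st.kruskal_wallis([[1, 2], [3, 4]]).statistic == pytest.approx(2.4)

    def test_identical_groups_zero(self):
        res = st.kruskal_wallis([[1.0, 2.0], [1.0, 2.0]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_all_identical_rejected(self):
        with pytest.raises(ValueError):
            st.kruskal_wallis([[5.0, 5.0], [5.0, 5.0]])

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_scipy_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        groups = [np.round(rng.normal(size=n), 1) for n in (12, 18, 9)]
        res = st.kruskal_wallis(groups)
        ref = sps.kruskal(*groups)
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p_raw == pytest.approx(ref.pvalue, rel=1e-9)

    def test_two_groups_equal_z_squared_from_mwu(self):
        # algebraic identity: H = z^2 of the tie-corrected MWU without
        # continuity correction
        rng = np.random.default_rng(9)
        a = rng.normal(size=30)
        b = np.round(rng.normal(size=25), 1)
        H = st.kruskal_wallis([a, b]).statistic
        pooled = np.concatenate([a, b])
        ranks = st.average_ranks(pooled)
        ua = ranks[:30].sum() - 30 * 31 / 2
        N = 55
        var = 30 * 25 / 12 * ((N + 1) - st._tie_term(pooled) / (N * (N - 1)))
        z = (ua - 30 * 25 / 2) / np.sqrt(var)
        assert H == pytest.approx(z * z, rel=1e-9)


class TestMannWhitney:
    def test_exact_enumeration_small(self):
        res = st.mann_whitney_u([1, 2], [3, 4])
        assert res.statistic == 0
        assert res.p_raw == pytest.approx(1 / 3)

    def test_identical_samples(self):
        res = st.mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_raw == pytest.approx(1.0)

    @pytest.mark.parametrize("sizes", [(6, 7), (10, 10), (18, 15)])
    def test_exact_matches_scipy(self, sizes):
        rng = np.random.default_rng(sum(sizes))
        a, b = rng.normal(size=sizes[0]), rng.normal(size=sizes[1])
        res = st.mann_whitney_u(a, b, mode="exact")
        ref = sps.mannwhitneyu(a, b, method="exact")
        assert res.p_raw == pytest.approx(ref.pvalue, rel=1e-12)

    def test_approx_matches_scipy(self):
        rng = np.random.default_rng(3)
        a = np.round(rng.normal(size=50), 1)
        b = np.round(rng.normal(size=60), 1)
        res = st.mann_whitney_u(a, b, mode="approx")
        ref = sps.mannwhitneyu(a, b, method="asymptotic", use_continuity=True)
        assert res.p_raw == pytest.approx(ref.pvalue, rel=1e-9)

    def test_exact_approx_agree_at_moderate_n(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=20) + 0.3
        b = rng.normal(size=20)
        ex = st.mann_whitney_u(a, b, mode="exact").p_raw
        ap = st.mann_whitney_u(a, b, mode="approx").p_raw
        assert abs(ex - ap) < 0.01

    def test_exact_requires_no_ties(self):
        with pytest.raises(ValueError):
            st.mann_whitney_u([1, 1, 2], [2, 3, 4], mode="exact")


class TestContingency:
    def test_chi2_proportional_table_is_zero(self):
        assert st.pearson_chi2([[10, 20, 30], [20, 40, 60]]).statistic == (
            pytest.approx(0.0, abs=1e-12)
        )

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_chi2_matches_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.integers(1, 50, size=(2, 3))
        res = st.pearson_chi2(t)
        total = t.sum()
        stat = 0.0
        for i in range(2):
            for j in range(3):
                e = t[i].sum() * t[:, j].sum() / total
                stat += (t[i, j] - e) ** 2 / e
        assert res.statistic == pytest.approx(stat, abs=1e-12)

    def test_chi2_permutation_invariance(self):
        t = np.array([[5, 9, 2], [7, 3, 11]])
        base = st.pearson_chi2(t).statistic
        assert st.pearson_chi2(t[:, [2, 0, 1]]).statistic == pytest.approx(base)
        assert st.pearson_chi2(t[[1, 0]]).statistic == pytest.approx(base)

    def test_fisher_2x2_full_enumeration(self):
        res = st.fisher_exact([[3, 1], [1, 3]])
        assert res.p_raw == pytest.approx(34 / 70)
        ref = sps.fisher_exact([[3, 1], [1, 3]])
        assert res.p_raw == pytest.approx(ref.pvalue)

    @pytest.mark.parametrize("table", [
        [[5, 2], [3, 9]], [[10, 3], [2, 8]], [[1, 7], [6, 2]],
    ])
    def test_fisher_matches_scipy_2x2(self, table):
        assert st.fisher_exact(table).p_raw == pytest.approx(
            sps.fisher_exact(table).pvalue, rel=1e-9
        )

    def test_freeman_halton_matches_r_reference(self):
        # fisher.test(matrix(c(4,1,3,2,6,5), nrow=2, byrow=TRUE))$p.value
        res = st.fisher_exact([[4, 1, 3], [2, 6, 5]])
        assert res.p_raw == pytest.approx(0.2068111, abs=1e-6)
        assert res.extra["method"] == "freeman-halton"

    def test_freeman_halton_reduces_to_2x2_rule(self):
        # padding a 2x2 with an all-zero column is infeasible, so compare
        # the 2-column path against the same table run through enumeration
        t = [[6, 2], [3, 7]]
        assert st.fisher_exact(t).p_raw == pytest.approx(
            sps.fisher_exact(t).pvalue, rel=1e-9
        )

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            st.fisher_exact([[0, 0], [1, 2]])

    def test_choose_test_expected_count_rule(self):
        # X-chromosome composition: smallest expected cell < 5 -> fisher
        assert st.choose_test([[27, 5, 8], [379, 52, 494]]) == "fisher"
        # immunity composition: all expected counts >= 5 -> chi2
        assert st.choose_test([[130, 11, 140], [276, 46, 362]]) == "chi2"
        assert st.choose_test([[50, 50], [50, 50]]) == "chi2"


class TestHolm:
    def test_hand_stepdown(self):
        assert st.holm_adjust([0.01, 0.04, 0.03]) == pytest.approx(
            [0.03, 0.06, 0.06]
        )

    def test_single_and_saturated(self):
        assert st.holm_adjust([0.2], m=1) == [pytest.approx(0.2)]
        assert st.holm_adjust([1.0, 1.0]) == [1.0, 1.0]

    def test_family_larger_than_list(self):
        # m may exceed the list length (family includes variant recalculations)
        assert st.holm_adjust([0.01], m=6) == [pytest.approx(0.06)]
        with pytest.raises(ValueError):
            st.holm_adjust([0.01, 0.02], m=1)

    @given(hst.lists(hst.floats(min_value=0, max_value=1), min_size=1,
                     max_size=10))
    @settings(max_examples=50, deadline=None)
    def test_bounded_by_raw_and_bonferroni(self, p):
        adj = st.holm_adjust(p)
        m = len(p)
        for raw, a in zip(p, adj):
            assert a >= raw - 1e-15
            assert a <= min(1.0, m * raw) + 1e-12

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=9)
        assert np.allclose(st.holm_adjust(p),
                           smm.multipletests(p, method="holm")[1])


class TestBootstrap:
    def test_constant_sample(self):
        assert st.bootstrap_median_ci([4.0] * 12, B=500, seed=0) == (4.0, 4.0)

    def test_interval_contains_sample_median(self):
        lo, hi = st.bootstrap_median_ci(np.arange(1.0, 10.0), B=100_000, seed=1)
        assert lo <= 5.0 <= hi

    def test_width_shrinks_with_n(self):
        rng = np.random.default_rng(2)
        small = rng.normal(size=20)
        big = rng.normal(size=2000)
        lo1, hi1 = st.bootstrap_median_ci(small, B=4000, seed=3)
        lo2, hi2 = st.bootstrap_median_ci(big, B=4000, seed=3)
        assert (hi2 - lo2) < (hi1 - lo1)

    def test_reproducible_from_seed(self):
        x = np.random.default_rng(5).exponential(size=40)
        assert st.bootstrap_median_ci(x, B=2000, seed=9) == (
            st.bootstrap_median_ci(x, B=2000, seed=9)
        )
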