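"""Group statistics against enumeration/permutation oracles and hand fixtures."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata, chi2 as chi2_dist

from vasquant import stats as st
from vasquant.simulate import generate_expression_matrix


def mwu_exact_p_by_enumeration(x, y):
    """Full enumeration over all C(n+m, n) group assignments (no ties)."""
    pooled = np.concatenate([x, y])
    n, total = len(x), len(pooled)
    ranks = rankdata(pooled)
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    us = np.array([ranks[list(idx)].sum() - n * (n + 1) / 2
                   for idx in combinations(range(total), n)])
    p = min(1.0, 2 * min((us <= u_obs).mean(), (us >= u_obs).mean()))
    return u_obs, p


class TestMannWhitney:
    def test_fully_separated_worked_example(self):
        res = st.mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1)  # 2 / C(6, 3)
        assert res.method == "mann-whitney-exact"

    def test_identical_constant_samples(self):
        res = st.mann_whitney_u([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
        assert res.statistic == 4.5  # nm / 2
        assert res.p_value == pytest.approx(1.0)

    def test_exact_equals_enumeration_over_random_inputs(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            n = int(rng.integers(1, 6))
            m = int(rng.integers(1, 10 - n + 1))
            x, y = rng.normal(size=n), rng.normal(size=m)
            u, p = mwu_exact_p_by_enumeration(x, y)
            res = st.mann_whitney_u(x, y)
            assert res.method == "mann-whitney-exact"
            assert res.statistic == pytest.approx(u)
            assert res.p_value == pytest.approx(p, abs=1e-12)

    def test_exact_and_approximate_agree_moderately(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            x, y = rng.normal(size=6), rng.normal(size=6)
            _, p_exact = mwu_exact_p_by_enumeration(x, y)
            from scipy.stats import mannwhitneyu
            p_approx = mannwhitneyu(x, y, method="asymptotic").pvalue
            assert abs(p_exact - p_approx) < 0.02

    def test_ties_dispatch_to_asymptotic(self):
        res = st.mann_whitney_u([1, 1, 2], [2, 3, 3])
        assert res.method == "mann-whitney-asymptotic"
        assert res.flags["ties"]

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            st.mann_whitney_u([], [1.0])


class TestKruskalWallis:
    def test_two_groups_match_mwu_normal_approximation(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=15), rng.normal(0.5, 1, size=15)
        kw = st.kruskal_wallis(x, y)
        from scipy.stats import mannwhitneyu
        p_mwu = mannwhitneyu(x, y, method="asymptotic").pvalue
        assert abs(kw.p_value - p_mwu) < 0.02

    def test_identical_groups_degenerate(self):
        res = st.kruskal_wallis([3.0, 3.0], [3.0, 3.0, 3.0])
        assert res.statistic == 0.0
        assert res.p_value == 1.0
        assert res.flags.get("degenerate")

    def test_three_disjoint_groups_significant_and_match_permutation(self):
        g1, g2, g3 = [1, 2, 3, 4, 5], [11, 12, 13, 14, 15], [21, 22, 23, 24, 25]
        res = st.kruskal_wallis(g1, g2, g3)
        assert res.p_value < 0.01
        # permutation oracle on the H statistic
        rng = np.random.default_rng(0)
        ranks = rankdata(np.r_[g1, g2, g3])
        sizes = [5, 5, 5]
        N = 15

        def h_stat(r):
            start, h = 0, 0.0
            for s in sizes:
                h += r[start:start + s].sum() ** 2 / s
                start += s
            return 12 / (N * (N + 1)) * h - 3 * (N + 1)

        h_obs = h_stat(ranks)
        count = 0
        n_perm = 20_000
        for _ in range(n_perm):
            count += h_stat(rng.permutation(ranks)) >= h_obs - 1e-12
        assert count / n_perm < 0.01

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError):
            st.kruskal_wallis([1.0, 2.0])


class TestChi2Yates:
    def test_worked_example(self):
        res = st.chi2_yates([[10, 20], [20, 10]])
        assert res.statistic == pytest.approx(5.4)  # 4 x (4.5^2 / 15)
        assert res.p_value == pytest.approx(chi2_dist.sf(5.4, 1))

    def test_balanced_table_null(self):
        res = st.chi2_yates([[5, 5], [5, 5]])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_invariant_to_transposition(self):
        t = np.array([[7, 3], [2, 9]])
        assert st.chi2_yates(t).statistic == pytest.approx(st.chi2_yates(t.T).statistic)

    def test_yates_never_exceeds_uncorrected(self):
        from scipy.stats import chi2_contingency
        rng = np.random.default_rng(1)
        for _ in range(50):
            t = rng.integers(1, 30, (2, 2))
            corrected = st.chi2_yates(t).statistic
            plain = chi2_contingency(t, correction=False).statistic
            assert corrected <= plain + 1e-12

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            st.chi2_yates([[0, 0], [5, 5]])


class TestPairwiseProportions:
    def test_identical_proportions_all_adjusted_one(self):
        out = st.pairwise_prop_test([10, 10, 10], [20, 20, 20])
        assert np.allclose(out["p_adj"], 1.0)

    def test_two_groups_adjustment_is_identity(self):
        out = st.pairwise_prop_test([5, 15], [20, 20])
        assert out["p_adj"].iloc[0] == pytest.approx(out["p_raw"].iloc[0])

    def test_holm_step_down_hand_fixture(self):
        from statsmodels.stats.multitest import multipletests
        raw = np.array([0.01, 0.02, 0.9])
        _, adj, _, _ = multipletests(raw, method="holm")
        assert np.allclose(adj, [0.03, 0.04, 0.9])
        # the same step-down computed by hand inside the pairwise table
        out = st.pairwise_prop_test([2, 12, 11], [30, 30, 30])
        order = np.argsort(out["p_raw"].to_numpy())
        m = len(out)
        running = 0.0
        for rank, idx in enumerate(order):
            expect = min(1.0, (m - rank) * out["p_raw"].iloc[idx])
            running = max(running, expect)
            assert out["p_adj"].iloc[idx] == pytest.approx(running)

    def test_adjusted_monotone_and_at_least_raw(self):
        out = st.pairwise_prop_test([1, 10, 19, 5], [20, 20, 20, 20])
        assert (out["p_adj"] >= out["p_raw"] - 1e-12).all()
        ordered = out.sort_values("p_raw")
        assert ordered["p_adj"].is_monotonic_increasing

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            st.pairwise_prop_test([5], [10])


class TestTTest:
    def test_identical_samples(self):
        res = st.t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_example_pooled(self):
        res = st.t_test([1, 2, 3], [2, 3, 4], variant="student")
        assert res.statistic == pytest.approx(-1.2247, abs=5e-5)

    def test_welch_equals_student_for_equal_variance_and_n(self):
        x, y = [1.0, 2.0, 3.0, 4.0], [2.0, 3.0, 4.0, 5.0]
        s = st.t_test(x, y, "student")
        w = st.t_test(x, y, "welch")
        assert s.statistic == pytest.approx(w.statistic)
        assert s.p_value == pytest.approx(w.p_value)

    def test_zero_variance_unequal_means_rejected(self):
        with pytest.raises(ValueError):
            st.t_test([1.0, 1.0], [2.0, 2.0])


class TestDotplot:
    def test_all_zero_gene_flagged(self):
        expr, _ = generate_expression_matrix([("c1", 10)], [(0.0, 1.0)], seed=1)
        out = st.dotplot_summary(expr)
        assert out["percent_expressing"].iloc[0] == 0.0
        assert out["mean_expression"].iloc[0] == 0.0
        assert out["mean_undefined"].iloc[0]

    def test_hand_example_percent_and_mean(self):
        values = np.zeros((10, 1))
        values[:4, 0] = [1, 2, 3, 4]
        expr = st.ExpressionMatrix(values=values, genes=["g"],
                                   clusters=np.array(["c"] * 10))
        out = st.dotplot_summary(expr)
        assert out["percent_expressing"].iloc[0] == 40.0
        assert out["mean_expression"].iloc[0] == pytest.approx(2.5)

    def test_all_cells_mean_option(self):
        values = np.zeros((10, 1))
        values[:4, 0] = [1, 2, 3, 4]
        expr = st.ExpressionMatrix(values=values, genes=["g"],
                                   clusters=np.array(["c"] * 10))
        out = st.dotplot_summary(expr, mean_over="all")
        assert out["mean_expression"].iloc[0] == pytest.approx(1.0)

    def test_generator_fraction_recovered(self):
        expr, truth = generate_expression_matrix([("c1", 1000)], [(0.4, 2.0)],
                                                 seed=5)
        out = st.dotplot_summary(expr)
        assert abs(out["percent_expressing"].iloc[0] - 40.0) <= 4.0  # 3 sigma
        assert out["percent_expressing"].iloc[0] == \
            pytest.approx(truth["realized_percent"].iloc[0])

    def test_unknown_gene_rejected(self):
        expr, _ = generate_expression_matrix([("c1", 5)], [(0.5, 1.0)], seed=0)
        with pytest.raises(KeyError):
            st.dotplot_summary(expr, genes=["nope"])

    def test_group_sizes_sum_to_total(self):
        expr, _ = generate_expression_matrix(
            [("venous", 30), ("arterial", 20)],
            [(0.5, 1.0), (0.2, 1.0)], seed=3)
        out = st.dotplot_summary(expr)
        assert out["n_cells"].sum() == 50
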