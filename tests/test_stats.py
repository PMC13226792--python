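import numpy as np
import pytest
from scipy import stats as sps

from erpdyn.errors import InvalidArgumentError
from erpdyn.stats import (
    anova_power,
    anova_required_n,
    chi_square_contingency,
    dunn_sidak,
    fdr_bh,
    kruskal_wallis,
    kw_dunn,
    partial_corr,
    pearson_corr,
)


class TestKruskalWallis:
    def test_identical_groups_null(self, rng):
        g = rng.normal(size=12)
        res = kruskal_wallis([g, g.copy()])
        assert res.p > 0.9

    def test_maximal_separation_hand_ranks(self):
        # groups {1,2,3}, {101,102,103}, {201,202,203}: ranks are 1..9 in
        # blocks; H = 12/(N(N+1)) * sum n_i (Rbar_i - (N+1)/2)^2 with no ties
        groups = [[1, 2, 3], [101, 102, 103], [201, 202, 203]]
        n = 9
        rbar = [2.0, 5.0, 8.0]
        h_oracle = 12.0 / (n * (n + 1)) * sum(
            3 * (rb - (n + 1) / 2.0) ** 2 for rb in rbar)
        res = kruskal_wallis(groups)
        assert res.statistic == pytest.approx(h_oracle, abs=1e-10)
        assert res.df == 2

    def test_monotone_transform_invariance(self, rng):
        groups = [rng.normal(size=8) for _ in range(3)]
        h1 = kruskal_wallis(groups).statistic
        h2 = kruskal_wallis([np.exp(g) for g in groups]).statistic
        assert h1 == pytest.approx(h2, abs=1e-10)

    def test_all_identical_convention(self):
        with pytest.warns(UserWarning):
            res = kruskal_wallis([[5, 5], [5, 5], [5, 5]])
        assert res.p == 1.0

    def test_type_one_error_calibration(self):
        # null simulation: rejection rate at alpha=0.05 within 0.05 +- 0.015
        rng = np.random.default_rng(77)
        n_sim = 2000
        rejections = 0
        for _ in range(n_sim):
            groups = [rng.normal(size=20) for _ in range(3)]
            if kruskal_wallis(groups).p < 0.05:
                rejections += 1
        rate = rejections / n_sim
        assert 0.035 <= rate <= 0.065


class TestDunnSidak:
    def test_identical_groups(self, rng):
        g = rng.normal(size=10)
        for pw in dunn_sidak([g, g.copy(), g.copy()]):
            assert pw.p_adjusted > 0.95

    def test_sidak_closed_form(self):
        # m = 3 comparisons, raw p = 0.05 -> adjusted 1 - 0.95^3
        p_adj = 1.0 - (1.0 - 0.05) ** 3
        assert p_adj == pytest.approx(0.142625)

    def test_brute_force_small_dataset(self):
        # independent implementation of Dunn's z on a tied 3x4 dataset
        groups = [np.array([1.0, 2.0, 2.0, 5.0]),
                  np.array([3.0, 4.0, 4.0, 9.0]),
                  np.array([6.0, 7.0, 8.0, 8.0])]
        pooled = np.concatenate(groups)
        ranks = sps.rankdata(pooled)
        n = len(pooled)
        rbar = [ranks[:4].mean(), ranks[4:8].mean(), ranks[8:].mean()]
        _, counts = np.unique(pooled, return_counts=True)
        tie = np.sum(counts**3 - counts) / (12.0 * (n - 1))
        var = n * (n + 1) / 12.0 - tie
        res = dunn_sidak(groups)
        for pw in res:
            i, j = pw.pair
            z_oracle = (rbar[i] - rbar[j]) / np.sqrt(var * (1 / 4 + 1 / 4))
            p_oracle = 2 * sps.norm.sf(abs(z_oracle))
            assert pw.z == pytest.approx(z_oracle, abs=1e-8)
            assert pw.p == pytest.approx(p_oracle, abs=1e-8)
            assert pw.p_adjusted == pytest.approx(
                min(1.0, 1 - (1 - p_oracle) ** 3), abs=1e-8)

    def test_adjusted_geq_raw(self, rng):
        groups = [rng.normal(loc=i, size=10) for i in range(3)]
        for pw in dunn_sidak(groups):
            assert pw.p_adjusted >= pw.p - 1e-12

    def test_sidak_dominates_bonferroni(self, rng):
        # 1 - (1-p)^m <= m p for p in [0, 1]
        for p in rng.uniform(0, 1, size=200):
            for m in (2, 3, 6, 10):
                assert 1 - (1 - p) ** m <= m * p + 1e-12


class TestFdrBH:
    def test_all_small_ties(self):
        # for m equal p-values the step-up minimum is reached at rank m,
        # so every adjusted p equals p itself (statsmodels agrees)
        rejected, adjusted = fdr_bh([0.001] * 10)
        assert rejected.all()
        np.testing.assert_allclose(adjusted, 0.001)

    def test_single_p(self):
        rejected, adjusted = fdr_bh([0.03])
        assert adjusted[0] == pytest.approx(0.03)
        assert rejected[0]

    def test_brute_force_step_up(self):
        p = np.array([0.01, 0.02, 0.03, 0.5])
        rejected, adjusted = fdr_bh(p, q=0.05)
        # step-up: largest k with p_(k) <= k q / m ; here k = 3
        m = 4
        expected_rejected = [True, True, True, False]
        np.testing.assert_array_equal(rejected, expected_rejected)
        # adjusted: min over j >= i of m p_(j) / j
        raw_adj = [0.04, 0.04, 0.04, 0.5]
        np.testing.assert_allclose(adjusted, raw_adj, atol=1e-12)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(0, 1, size=40)
        rejected, adjusted = fdr_bh(p, q=0.05)
        rej_sm, adj_sm, _, _ = multipletests(p, alpha=0.05, method="fdr_bh")
        np.testing.assert_array_equal(rejected, rej_sm)
        np.testing.assert_allclose(adjusted, adj_sm, atol=1e-12)

    def test_empty(self):
        rejected, adjusted = fdr_bh([])
        assert len(rejected) == 0 and len(adjusted) == 0

    def test_fdr_control_under_null(self):
        # independent null p-values: empirical FDR <= q
        rng = np.random.default_rng(99)
        q = 0.05
        false_discovery_total = 0
        for _ in range(2000):
            p = rng.uniform(0, 1, size=20)
            rejected, _ = fdr_bh(p, q=q)
            if rejected.any():
                false_discovery_total += 1   # all nulls: any rejection is false
        assert false_discovery_total / 2000 <= q + 0.015

    def test_invalid_p(self):
        with pytest.raises(InvalidArgumentError):
            fdr_bh([0.5, 1.5])


class TestCorrelations:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        r, p = pearson_corr(x, 2 * x + 1)
        assert r == pytest.approx(1.0)

    def test_partial_removes_confounder(self):
        # x and y driven only by z: partial r | z ~ 0
        rng = np.random.default_rng(42)
        z = rng.normal(size=1000)
        x = 2 * z + rng.normal(size=1000)
        y = -3 * z + rng.normal(size=1000)
        r_raw, _ = pearson_corr(x, y)
        r_part, _ = partial_corr(x, y, z)
        assert abs(r_raw) > 0.5
        assert abs(r_part) < 0.1

    def test_partial_no_covariates_is_pearson(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        assert partial_corr(x, y) == pytest.approx(pearson_corr(x, y))

    def test_partial_matches_pingouin_formula(self, rng):
        # recursion formula oracle for one covariate:
        # r_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2))
        x = rng.normal(size=50)
        z = rng.normal(size=50)
        y = x * 0.3 + z * 0.5 + rng.normal(size=50)
        r_xy, _ = pearson_corr(x, y)
        r_xz, _ = pearson_corr(x, z)
        r_yz, _ = pearson_corr(y, z)
        oracle = (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
        r_part, _ = partial_corr(x, y, z)
        assert r_part == pytest.approx(oracle, abs=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(InvalidArgumentError):
            pearson_corr(np.ones(10), np.arange(10.0))


class TestChiSquare:
    def test_printed_gender_table(self):
        res = chi_square_contingency([[52, 19], [44, 18], [32, 10]])
        assert round(res.p, 4) == 0.8402
        assert res.df == 2

    def test_proportional_table(self):
        res = chi_square_contingency([[10, 20], [20, 40], [5, 10]])
        assert res.statistic == pytest.approx(0.0, abs=1e-10)
        assert res.p == pytest.approx(1.0)

    def test_diagonal_2x2_oracle(self):
        res = chi_square_contingency([[10, 0], [0, 10]])
        assert res.statistic == pytest.approx(20.0)
        assert res.df == 1
        assert res.p == pytest.approx(sps.chi2.sf(20.0, 1), abs=1e-12)

    def test_zero_marginal_rejected(self):
        with pytest.raises(InvalidArgumentError):
            chi_square_contingency([[5, 0], [3, 0]])


class TestAnovaRequiredN:
    def test_reference_case(self):
        assert anova_required_n(0.25, 0.05, 0.80, 3) == 159

    def test_monotone_in_effect_size(self):
        n_small = anova_required_n(0.25, 0.05, 0.80, 3)
        n_large = anova_required_n(0.40, 0.05, 0.80, 3)
        assert n_large < n_small

    def test_against_power_integration_oracle(self):
        # independent oracle: P(F > crit) with F = (X1/df1)/(X2/df2),
        # X1 ~ noncentral chi2(df1, lambda), X2 ~ chi2(df2)
        from scipy import integrate

        def oracle_power(n, f, alpha, k):
            df1, df2 = k - 1, n - k
            lam = f * f * n
            crit = sps.f.isf(alpha, df1, df2)
            val, _ = integrate.quad(
                lambda x2: sps.ncx2.sf(crit * df1 / df2 * x2, df1, lam)
                * sps.chi2.pdf(x2, df2),
                0, np.inf, limit=200)
            return val

        n = anova_required_n(0.40, 0.05, 0.80, 3)
        assert oracle_power(n, 0.40, 0.05, 3) >= 0.80
        assert oracle_power(n - 3, 0.40, 0.05, 3) < 0.80
        assert anova_power(n, 0.40, 0.05, 3) == pytest.approx(
            oracle_power(n, 0.40, 0.05, 3), abs=1e-6)

    def test_unbalanced_search_158(self):
        # integer-step search reaches power one subject earlier
        assert anova_required_n(0.25, 0.05, 0.80, 3, balanced=False) == 158

    def test_invalid_inputs(self):
        with pytest.raises(InvalidArgumentError):
            anova_required_n(-0.2)
        with pytest.raises(InvalidArgumentError):
            anova_required_n(0.25, alpha=1.5)


class TestKwDunnBundle:
    def test_pairwise_attached(self, rng):
        groups = [rng.normal(loc=i, size=10) for i in range(3)]
        res = kw_dunn(groups)
        assert len(res.pairwise) == 3
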