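"""Multivariate-t MCTP: statistics, correlation, Box df, quantiles, p-values,
simultaneous intervals and the assembled test."""

import numpy as np
import pytest
from scipy import stats

from hetmctp import (
    AncovaData,
    DegenerateContrastError,
    adjusted_pvalues,
    box_df,
    build_contrast,
    correlation_matrix,
    equicoordinate_quantile,
    fit_ancova,
    max_abs_cdf,
    mctp_t_test,
    select_df,
    simultaneous_ci,
)
from hetmctp.mctp import test_statistics as contrast_statistics


def _welch_oracle(y1, y2):
    """Textbook Welch two-sample t statistic and Satterthwaite df."""
    n1, n2 = len(y1), len(y2)
    v1, v2 = np.var(y1, ddof=1), np.var(y2, ddof=1)
    se2 = v1 / n1 + v2 / n2
    t = (np.mean(y2) - np.mean(y1)) / np.sqrt(se2)
    df = se2 ** 2 / (v1 ** 2 / (n1 ** 2 * (n1 - 1)) + v2 ** 2 / (n2 ** 2 * (n2 - 1)))
    return t, df


class TestStatistics:
    def test_null_numerator_gives_zero(self):
        # group means (1, 2, 3) exactly, with within-group noise
        base = np.array([-1.0, 0.0, 1.0])
        y = np.concatenate([base + 1, base + 2, base + 3])
        data = AncovaData(y=y, groups=np.repeat([0, 1, 2], 3))
        fit = fit_ancova(data)
        T, _ = contrast_statistics(fit, build_contrast("tukey", 3))
        assert T[0] != 0  # 2 vs 1 differs
        # linear-trend contrast kills the equally spaced means
        from hetmctp.contrasts import ContrastMatrix
        Cc = ContrastMatrix(C=np.array([[1.0, -2.0, 1.0]]), row_labels=["lin"],
                            family="custom")
        Tc, _ = contrast_statistics(fit, Cc)
        assert Tc[0] == pytest.approx(0.0, abs=1e-12)

    def test_welch_statistic(self, welch_pair):
        fit = fit_ancova(welch_pair, mode="groupwise")
        C = build_contrast("dunnett", 2)
        T, T0 = contrast_statistics(fit, C)
        y1 = welch_pair.y[welch_pair.groups == "ctrl"]
        y2 = welch_pair.y[welch_pair.groups == "trt"]
        t_ref, _ = _welch_oracle(y1, y2)
        assert T[0] == pytest.approx(t_ref, abs=1e-10)
        assert T0 == pytest.approx(abs(t_ref), abs=1e-10)

    def test_zero_variance_contrast_raises(self, three_group):
        fit = fit_ancova(three_group)
        fit.Psi_hat[:] = 0.0
        with pytest.raises(DegenerateContrastError):
            contrast_statistics(fit, build_contrast("dunnett", 3))


class TestCorrelation:
    def test_unit_diagonal_random_psd(self, rng):
        X = rng.standard_normal((6, 4))
        Psi = X.T @ X
        C = build_contrast("tukey", 4)
        R = correlation_matrix(Psi, C)
        np.testing.assert_allclose(np.diag(R), 1.0, atol=1e-12)
        # elementwise cov-to-corr oracle
        V = C.C @ Psi @ C.C.T
        oracle = V / np.sqrt(np.outer(np.diag(V), np.diag(V)))
        np.testing.assert_allclose(R, oracle, atol=1e-10)

    def test_dunnett_balanced_correlation_half(self):
        # equal n, equal sigma2, no covariates -> off-diagonal exactly 0.5
        Psi = np.diag([1.0, 1.0, 1.0])
        R = correlation_matrix(Psi, build_contrast("dunnett", 3))
        assert R[0, 1] == pytest.approx(0.5, abs=1e-12)


class TestBoxDf:
    def test_welch_satterthwaite_limit(self, welch_pair):
        fit = fit_ancova(welch_pair, mode="groupwise")
        nu = box_df(fit, build_contrast("dunnett", 2))
        y1 = welch_pair.y[welch_pair.groups == "ctrl"]
        y2 = welch_pair.y[welch_pair.groups == "trt"]
        _, df_ref = _welch_oracle(y1, y2)
        assert nu[0] == pytest.approx(df_ref, abs=1e-10)

    def test_balanced_equal_variance_closed_form(self):
        # sigma1 = sigma2, n1 = n2 = n -> nu = 2(n - 1)
        n = 6
        y = np.concatenate([np.arange(n), np.arange(n) + 10.0])
        data = AncovaData(y=y, groups=np.repeat([0, 1], n))
        fit = fit_ancova(data, mode="groupwise")
        nu = box_df(fit, build_contrast("dunnett", 2))
        assert nu[0] == pytest.approx(2 * (n - 1), abs=1e-9)

    def test_grandmean_row_first_principles(self):
        # no covariates: D is the group-mean operator; rebuild the formula
        # symbolically for the first grand-mean row
        rng = np.random.default_rng(10)
        n = np.array([5, 7, 9])
        groups = np.repeat([0, 1, 2], n)
        y = rng.standard_normal(n.sum()) * np.array([1.0, 2.0, 0.5])[groups]
        data = AncovaData(y=y, groups=groups)
        fit = fit_ancova(data, mode="groupwise")
        C = build_contrast("grandmean", 3)
        nu = box_df(fit, C)
        s2 = fit.variance.group_sigma2
        c = C.C[0]
        # independent oracle: s_{l,i} = c_i^2 / n_i, variance = sum s_i s2_i
        s_li = c ** 2 / n
        var = s_li @ s2
        den = np.sum(s_li ** 2 * s2 ** 2 / (n - 1))
        assert nu[0] == pytest.approx(var ** 2 / den, rel=1e-10)


class TestSelectDf:
    @pytest.mark.parametrize("rule,expected", [
        ("mean", 4.0), ("min", 3.2), ("max", 5.8),
    ])
    def test_rules(self, rule, expected):
        assert select_df(np.array([3.2, 5.8, 4.0]), rule) == expected

    def test_mean_rounds_half_away_from_zero(self):
        assert select_df(np.array([3.5, 3.5]), "mean") == 4.0

    def test_ordering(self, rng):
        cand = rng.uniform(2, 40, size=7)
        assert select_df(cand, "min") <= select_df(cand, "mean") + 0.5
        assert select_df(cand, "mean") <= select_df(cand, "max") + 0.5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_df(np.array([]), "mean")


class TestEquicoordinateQuantile:
    def test_univariate_normal(self):
        R = np.eye(1)
        assert equicoordinate_quantile(R, np.inf, 0.05) == pytest.approx(
            1.959964, abs=1e-5
        )

    def test_independent_bivariate_closed_form(self):
        # P(max(|Z1|,|Z2|) <= z) = (2 Phi(z) - 1)^2 for R = I
        z_ref = stats.norm.ppf((1 + np.sqrt(0.95)) / 2)
        z = equicoordinate_quantile(np.eye(2), np.inf, 0.05)
        assert z == pytest.approx(z_ref, abs=1e-3)

    def test_trivariate_t_monte_carlo_oracle(self):
        R = np.full((3, 3), 0.5)
        np.fill_diagonal(R, 1.0)
        crit = equicoordinate_quantile(R, 10.0, 0.05)
        rng = np.random.default_rng(42)
        L = np.linalg.cholesky(R)
        z = rng.standard_normal((1_000_000, 3)) @ L.T
        s = np.sqrt(rng.chisquare(10, 1_000_000) / 10)
        mx = np.abs(z / s[:, None]).max(axis=1)
        assert crit == pytest.approx(np.quantile(mx, 0.95), abs=0.01)

    def test_monotone_in_alpha_and_correlation(self):
        R0 = np.eye(2)
        quantiles = [equicoordinate_quantile(R0, np.inf, a)
                     for a in (0.01, 0.05, 0.10, 0.20)]
        assert np.all(np.diff(quantiles) < 0)
        crits = []
        for rho in (0.0, 0.3, 0.6, 0.9):
            R = np.array([[1.0, rho], [rho, 1.0]])
            crits.append(equicoordinate_quantile(R, np.inf, 0.05))
        assert np.all(np.diff(crits) < 1e-4)  # non-increasing in |rho|

    def test_contract_errors(self):
        with pytest.raises(ValueError, match="unit diagonal"):
            equicoordinate_quantile(np.array([[2.0, 0.0], [0.0, 1.0]]),
                                    np.inf, 0.05)
        with pytest.raises(ValueError, match="alpha"):
            equicoordinate_quantile(np.eye(2), np.inf, 1.5)

    def test_singular_grandmean_t_vs_monte_carlo(self):
        # rank-deficient correlation from the grand-mean family
        a = 4
        P = np.eye(a) - np.ones((a, a)) / a
        d = np.sqrt(np.diag(P))
        R = P / np.outer(d, d)
        crit = equicoordinate_quantile(R, 20.0, 0.05)
        w, V = np.linalg.eigh(R)
        L = V * np.sqrt(np.clip(w, 0, None))
        rng = np.random.default_rng(3)
        z = rng.standard_normal((1_000_000, a)) @ L.T
        s = np.sqrt(rng.chisquare(20, 1_000_000) / 20)
        mx = np.abs(z / s[:, None]).max(axis=1)
        assert crit == pytest.approx(np.quantile(mx, 0.95), abs=0.01)


class TestAdjustedPvalues:
    def test_single_contrast_reduces_to_univariate_t(self):
        p = adjusted_pvalues(np.array([2.1]), np.eye(1), 12.0)
        assert p[0] == pytest.approx(2 * stats.t.sf(2.1, 12), abs=1e-12)

    def test_zero_statistic_gives_one(self):
        p = adjusted_pvalues(np.array([0.0, 1.0]), np.eye(2), np.inf)
        assert p[0] == pytest.approx(1.0, abs=1e-12)

    def test_independent_bivariate_closed_form(self):
        T = np.array([2.0, 1.0])
        p = adjusted_pvalues(T, np.eye(2), np.inf)
        ref = 1 - (2 * stats.norm.cdf(np.abs(T)) - 1) ** 2
        np.testing.assert_allclose(p, ref, atol=1e-4)


class TestSimultaneousCi:
    def test_geometry(self, three_group):
        C = build_contrast("tukey", 3)
        fit = fit_ancova(three_group)
        sci = simultaneous_ci(fit, C, 2.5)
        delta = C.C @ fit.b_hat
        assert np.all(sci[:, 0] <= delta) and np.all(delta <= sci[:, 1])
        wide = simultaneous_ci(fit, C, 5.0)
        np.testing.assert_allclose(
            wide[:, 1] - wide[:, 0], 2 * (sci[:, 1] - sci[:, 0]), rtol=1e-12
        )


class TestMctpTTest:
    def test_two_sample_welch_p_value(self, welch_pair):
        res = mctp_t_test(welch_pair, build_contrast("dunnett", 2),
                          df_rule="min")
        y1 = welch_pair.y[welch_pair.groups == "ctrl"]
        y2 = welch_pair.y[welch_pair.groups == "trt"]
        ref = stats.ttest_ind(y2, y1, equal_var=False)
        assert res.statistics[0] == pytest.approx(ref.statistic, abs=1e-6)
        assert res.df_used == pytest.approx(ref.df, abs=1e-6)
        assert res.p_adjusted[0] == pytest.approx(ref.pvalue, abs=1e-3)

    def test_determinism(self, three_group):
        C = build_contrast("tukey", 3)
        r1 = mctp_t_test(three_group, C)
        r2 = mctp_t_test(three_group, C)
        assert r1.critical == r2.critical
        np.testing.assert_array_equal(r1.p_adjusted, r2.p_adjusted)
        np.testing.assert_array_equal(r1.sci, r2.sci)

    def test_df_rule_ordering_implies_critical_ordering(self, three_group):
        C = build_contrast("tukey", 3)
        crits = {rule: mctp_t_test(three_group, C, df_rule=rule).critical
                 for rule in ("min", "mean", "max", "asymptotic")}
        assert crits["min"] >= crits["mean"] - 1e-3
        assert crits["mean"] >= crits["max"] - 1.0  # mean rounds to integer
        assert crits["max"] >= crits["asymptotic"] - 1e-3

    def test_consonance_and_compatibility(self, rng):
        # randomized fixtures: global decision, individual decisions, adjusted
        # p-values and SCI zero-exclusion must tell one coherent story
        for _ in range(25):
            n = rng.integers(6, 12)
            groups = np.repeat([0, 1, 2], n)
            y = rng.standard_normal(3 * n) + rng.choice([0, 1.0]) * (groups == 0)
            data = AncovaData(y=y, groups=groups,
                              covariates=rng.normal(7, 1, (3 * n, 1)))
            res = mctp_t_test(data, build_contrast("dunnett", 3))
            assert res.reject_global == res.reject.any()
            np.testing.assert_array_equal(
                res.reject, np.abs(res.statistics) >= res.critical
            )
            excl = (res.sci[:, 0] > 0) | (res.sci[:, 1] < 0)
            np.testing.assert_array_equal(excl, res.reject)
            if abs(res.p_adjusted.min() - res.alpha) > 2e-3:
                assert res.reject_global == (res.p_adjusted.min() <= res.alpha)

    def test_asymptotic_mode_skips_box_df(self, three_group):
        res = mctp_t_test(three_group, build_contrast("dunnett", 3),
                          df_rule="asymptotic")
        assert res.df_candidates is None
        assert np.isinf(res.df_used)
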