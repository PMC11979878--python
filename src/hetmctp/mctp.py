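"""Multivariate-t multiple contrast test procedure (MCTP) for heteroscedastic
ANCOVA.

The vector of standardized contrast statistics
``T_l = c_l' b_hat / sqrt(c_l' Psi_hat c_l)`` is asymptotically multivariate
normal with correlation matrix ``R = cov2corr(C Psi C')``.  For small samples
under group-wise heteroscedasticity the joint law is approximated by a central
multivariate t distribution whose degrees of freedom come from a Box/
Satterthwaite moment match of each contrast variance to a scaled chi-square,
collapsed to a single value by the min / mean / max rule.  Critical values are
two-sided equicoordinate quantiles, p-values come from the distribution of
``max_l |T_l|``, and the compatible simultaneous confidence intervals are
``c_l' b_hat +/- t_crit * sqrt(c_l' Psi_hat c_l)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import optimize, stats

from .contrasts import ContrastMatrix
from .model import AncovaData, DesignMatrices, FitResult, VarianceEstimate, fit_ancova

# fixed internal seed of the randomized-QMC rectangle-probability integration;
# makes quantiles, p-values and SCIs bit-reproducible across runs
_QMC_SEED = 186283

DF_RULES = ("min", "mean", "max", "asymptotic")


class DegenerateContrastError(ValueError):
    """A contrast has zero estimated variance."""


@dataclass
class MctpTResult:
    """Result of the multivariate-t MCTP."""

    estimates: np.ndarray
    statistics: np.ndarray
    T0: float
    R_hat: np.ndarray
    df_candidates: Optional[np.ndarray]
    df_used: float
    df_rule: str
    critical: float
    p_adjusted: np.ndarray
    sci: np.ndarray
    alpha: float
    reject: np.ndarray
    reject_global: bool
    row_labels: list
    fit: FitResult


def test_statistics(fit: FitResult, C: ContrastMatrix):
    """Standardized contrast statistics ``T_l`` and their maximum ``T0``."""
    delta = C.C @ fit.b_hat
    var = np.einsum("ij,jk,ik->i", C.C, fit.Psi_hat, C.C)
    bad = np.where(var <= 0)[0]
    if bad.size:
        raise DegenerateContrastError(
            f"zero estimated variance for contrast row(s) "
            f"{[C.row_labels[i] for i in bad]}"
        )
    T = delta / np.sqrt(var)
    return T, float(np.max(np.abs(T)))


def correlation_matrix(Psi_hat: np.ndarray, C: ContrastMatrix) -> np.ndarray:
    """Correlation matrix of the contrast statistics, ``cov2corr(C Psi C')``."""
    V = C.C @ Psi_hat @ C.C.T
    d = np.diag(V)
    bad = np.where(d <= 0)[0]
    if bad.size:
        raise DegenerateContrastError(
            f"zero variance on the diagonal of C Psi C' for row(s) "
            f"{[C.row_labels[i] for i in bad]}"
        )
    s = 1.0 / np.sqrt(d)
    R = V * np.outer(s, s)
    R = 0.5 * (R + R.T)
    np.fill_diagonal(R, 1.0)
    return np.clip(R, -1.0, 1.0)


def box_df(fit: FitResult, C: ContrastMatrix) -> np.ndarray:
    """Per-contrast Satterthwaite degrees of freedom.

    With ``w_l = c_l' D`` and ``s_{l,i}`` the within-group-i sum of the
    squared entries of ``w_l``, the estimated contrast variance
    ``c_l' Psi_hat c_l = sum_i s_{l,i} sigma2_i`` is matched to a scaled
    chi-square, giving

        nu_l = (c_l' Psi_hat c_l)^2
               / sum_i s_{l,i}^2 sigma2_i^2 / (n_i - 1 - rank(M_i)).

    In the two-sample no-covariate case this is exactly the Welch-
    Satterthwaite formula.
    """
    variance = fit.variance
    if variance.mode != "groupwise" or variance.group_df is None:
        raise ValueError("Box df requires the group-wise variance estimator")
    W = C.C @ fit.D                                   # q x N
    a = fit.design.n_groups
    S = np.zeros((C.q, a))
    np.add.at(S.T, fit.design.group_codes, (W ** 2).T)  # s_{l,i}
    num = (S @ variance.group_sigma2) ** 2
    den = (S ** 2) @ (variance.group_sigma2 ** 2 / variance.group_df)
    if np.any(den <= 0):
        raise DegenerateContrastError("degenerate contrast variance in Box df")
    return num / den


def select_df(df_candidates: np.ndarray, rule: str) -> float:
    """Collapse the per-contrast df candidates with the min / mean / max rule.

    ``min`` and ``max`` return the extreme candidate unrounded; ``mean``
    returns the arithmetic mean rounded to the nearest integer (half away
    from zero).
    """
    df_candidates = np.asarray(df_candidates, dtype=float)
    if df_candidates.size == 0:
        raise ValueError("empty degrees-of-freedom candidates")
    if rule == "min":
        return float(df_candidates.min())
    if rule == "max":
        return float(df_candidates.max())
    if rule == "mean":
        m = float(df_candidates.mean())
        return float(np.floor(m + 0.5)) if m >= 0 else -float(np.floor(-m + 0.5))
    raise ValueError(f"unknown df rule {rule!r}")


def _check_correlation(R: np.ndarray) -> np.ndarray:
    R = np.atleast_2d(np.asarray(R, dtype=float))
    if np.any(np.abs(np.diag(R) - 1.0) > 1e-8):
        raise ValueError("correlation matrix must have unit diagonal")
    if np.min(np.linalg.eigvalsh(0.5 * (R + R.T))) < -1e-8:
        raise ValueError("correlation matrix is not positive semi-definite")
    return 0.5 * (R + R.T)


_sobol_max_cache: dict = {}


def _sobol_max_profile(R: np.ndarray, log2_points: int) -> np.ndarray:
    """Cached ``max_l |(L u)_l|`` over a scrambled Sobol net, with ``L`` a
    rank-r factor of ``R``.  The net is deterministic (fixed seed)."""
    key = (R.tobytes(), R.shape[0], log2_points)
    m = _sobol_max_cache.get(key)
    if m is None:
        w, V = np.linalg.eigh(R)
        keep = w > 1e-12 * w.max()
        L = V[:, keep] * np.sqrt(w[keep])
        sob = stats.qmc.Sobol(d=L.shape[1], scramble=True, seed=_QMC_SEED)
        u = stats.norm.ppf(sob.random(2 ** log2_points))
        m = np.max(np.abs(u @ L.T), axis=1)
        if len(_sobol_max_cache) > 32:
            _sobol_max_cache.clear()
        _sobol_max_cache[key] = m
    return m


def _singular_t_rectangle(t: float, R: np.ndarray, nu: float,
                          log2_points: int = 15) -> float:
    """``P(max_l |T_l| <= t)`` for t(nu, R) with a rank-deficient R.

    Writes ``T = L u / s`` with ``R = L L'`` (rank-r factor), ``u`` standard
    normal and ``s^2 = chi2_nu / nu``.  Conditional on ``u``,
    ``max|T| <= t  <=>  chi2 >= nu (max|L u| / t)^2``, so the chi-square
    dimension integrates analytically and only the smooth r-dimensional
    integrand is averaged over a scrambled Sobol net (fixed seed).
    """
    m = _sobol_max_profile(R, log2_points)
    return float(np.mean(stats.chi2.sf(nu * (m / t) ** 2, nu)))


def max_abs_cdf(t: float, R: np.ndarray, nu: float) -> float:
    """``P(max_l |Z_l| <= t)`` for central multivariate t(nu, R) (normal for
    ``nu = inf``), via randomized-QMC rectangle probabilities with a fixed
    internal seed.

    Nonsingular R uses the Genz algorithm; a singular R with finite ``nu``
    falls back to a deterministic Sobol integration because the Genz
    multivariate-t path mishandles rank-deficient shape matrices.
    """
    q = R.shape[0]
    if t <= 0:
        return 0.0
    if q == 1:
        if np.isinf(nu):
            return float(2.0 * stats.norm.cdf(t) - 1.0)
        return float(2.0 * stats.t.cdf(t, df=nu) - 1.0)
    upper = np.full(q, float(t))
    if np.isinf(nu):
        p = stats.multivariate_normal.cdf(
            upper, cov=R, allow_singular=True, lower_limit=-upper,
            rng=np.random.default_rng(_QMC_SEED),
        )
    else:
        eigs = np.linalg.eigvalsh(R)
        if eigs.min() <= 1e-10 * eigs.max():
            p = _singular_t_rectangle(t, R, nu)
        else:
            p = stats.multivariate_t.cdf(
                upper, shape=R, df=nu, lower_limit=-upper,
                random_state=np.random.default_rng(_QMC_SEED),
            )
    return float(min(max(p, 0.0), 1.0))


def equicoordinate_quantile(R: np.ndarray, nu: float, alpha: float) -> float:
    """Two-sided (1 - alpha) equicoordinate quantile of the central
    multivariate t(nu, R) (normal when ``nu = inf``).

    The root of ``P(max|Z| <= t) = 1 - alpha`` is found by bracketing between
    the unadjusted and the Bonferroni-adjusted univariate two-sided quantile.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie strictly between 0 and 1")
    R = _check_correlation(R)
    q = R.shape[0]
    dist = stats.norm if np.isinf(nu) else stats.t(df=nu)
    if q == 1:
        return float(dist.ppf(1.0 - alpha / 2.0))
    lo = float(dist.ppf(1.0 - alpha / 2.0))
    hi = float(dist.ppf(1.0 - alpha / (2.0 * q)))  # Bonferroni bound
    target = 1.0 - alpha
    f = lambda t: max_abs_cdf(t, R, nu) - target
    flo, fhi = f(lo), f(hi)
    if flo >= 0.0:
        return lo
    while fhi < 0.0:  # QMC noise can leave the Bonferroni bound marginally low
        hi *= 1.25
        fhi = f(hi)
    return float(optimize.brentq(f, lo, hi, xtol=1e-6, rtol=1e-12))


def adjusted_pvalues(statistics: np.ndarray, R: np.ndarray, nu: float) -> np.ndarray:
    """Single-step adjusted p-values ``p_l = 1 - P(max_j |Z_j| <= |T_l|)``."""
    R = _check_correlation(R)
    stats_abs = np.abs(np.asarray(statistics, dtype=float))
    return np.array([1.0 - max_abs_cdf(t, R, nu) for t in stats_abs])


def simultaneous_ci(fit: FitResult, C: ContrastMatrix, critical: float) -> np.ndarray:
    """Compatible simultaneous confidence intervals
    ``c_l' b_hat +/- critical * sqrt(c_l' Psi_hat c_l)``."""
    if critical <= 0:
        raise ValueError("critical value must be positive")
    delta = C.C @ fit.b_hat
    half = critical * np.sqrt(np.einsum("ij,jk,ik->i", C.C, fit.Psi_hat, C.C))
    return np.column_stack([delta - half, delta + half])


def mctp_t_test(data: AncovaData, C: ContrastMatrix, alpha: float = 0.05,
                df_rule: str = "mean") -> MctpTResult:
    """Run the multivariate-t MCTP on an ANCOVA dataset.

    ``df_rule='asymptotic'`` skips the Box approximation and uses the
    multivariate normal reference (``nu = inf``).  The other rules use the
    group-wise variance estimator with GLS plug-in effects.
    """
    if df_rule not in DF_RULES:
        raise ValueError(f"df_rule must be one of {DF_RULES}")
    fit = fit_ancova(data, mode="groupwise", estimator="gls_plugin")
    if C.a != data.n_groups:
        raise ValueError(
            f"contrast matrix has {C.a} columns but the data has "
            f"{data.n_groups} cells"
        )
    T, T0 = test_statistics(fit, C)
    R_hat = correlation_matrix(fit.Psi_hat, C)
    if df_rule == "asymptotic":
        df_candidates = None
        nu = np.inf
    else:
        df_candidates = box_df(fit, C)
        nu = select_df(df_candidates, df_rule)
    critical = equicoordinate_quantile(R_hat, nu, alpha)
    p_adj = adjusted_pvalues(T, R_hat, nu)
    sci = simultaneous_ci(fit, C, critical)
    reject = np.abs(T) >= critical
    return MctpTResult(
        estimates=C.C @ fit.b_hat, statistics=T, T0=T0, R_hat=R_hat,
        df_candidates=df_candidates, df_used=float(nu), df_rule=df_rule,
        critical=critical, p_adjusted=p_adj, sci=sci, alpha=alpha,
        reject=reject, reject_global=bool(reject.any()),
        row_labels=list(C.row_labels), fit=fit,
    )
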