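"""Monte-Carlo engine for the type-I-error and power study.

Data are generated from ``Y_ik = b_i + M_ik' p + sigma_ik (Z_ik - EZ)/sd(Z)``
with four N(7, 1) covariates, coefficients ``p = (0.2, 1, 1.5, 2)`` and a
baseline effect of 7.  Errors come from one of four standardized parent
distributions (normal, t5, chi-square(12), Exp(1)); variances are
homoscedastic, group-wise (sigma = (sigma1, 1.5, 1, 0.5, 0.75) truncated to
``a`` groups) or completely heteroscedastic (sigma_ik ~ U(0.5, 4)).  Sample
sizes are balanced (8, ..., 8) + r or unbalanced (8, 10, 13, 17, 20) + r with
negative pairing (largest variance with smallest n) or its reverse with
positive pairing.  Alternatives shift the first group by -delta (alt1) and
additionally the second by +delta (alt2).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence

import numpy as np

from .bootstrap import boot_mctp
from .contrasts import ContrastMatrix, build_contrast
from .mctp import box_df, correlation_matrix, max_abs_cdf, select_df, test_statistics
from .model import AncovaData, fit_ancova

COVARIATE_EFFECTS = np.array([0.2, 1.0, 1.5, 2.0])
BASELINE_EFFECT = 7.0
GROUPWISE_SIGMA_TAIL = np.array([1.5, 1.0, 0.5, 0.75])  # sigma_2..sigma_5

ERROR_DISTS = ("normal", "t5", "chisq12", "exp1")
N_SCHEMES = ("balanced", "unbalanced_np", "unbalanced_pp")
VARIANCES = ("homoscedastic", "groupwise", "complete")
METHODS = ("t_min", "t_mean", "t_max", "asymptotic", "boot")


@dataclass
class SimConfig:
    """One simulation scenario: design, error law, variance regime, method."""

    a: int = 3
    n_scheme: str = "balanced"
    r: int = 0
    error_dist: str = "normal"
    variance: str = "homoscedastic"
    sigma1: float = 2.0
    contrast: str = "dunnett"
    method: str = "t_mean"
    alpha: float = 0.05
    nsim: int = 5000
    nboot: int = 1000
    seed: Optional[int] = None
    alternative: str = "null"
    delta: float = 0.0

    def __post_init__(self):
        if not 2 <= self.a <= 5:
            raise ValueError("a must be between 2 and 5 (printed vectors)")
        if self.n_scheme not in N_SCHEMES:
            raise ValueError(f"unknown n_scheme {self.n_scheme!r}")
        if self.error_dist not in ERROR_DISTS:
            raise ValueError(f"unknown error distribution {self.error_dist!r}")
        if self.variance not in VARIANCES:
            raise ValueError(f"unknown variance regime {self.variance!r}")
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.alternative not in ("null", "alt1", "alt2"):
            raise ValueError(f"unknown alternative {self.alternative!r}")
        if self.alternative != "null" and not 0.0 <= self.delta <= 2.0:
            raise ValueError("delta must lie in [0, 2]")

    def sample_sizes(self) -> np.ndarray:
        if self.n_scheme == "balanced":
            base = np.full(self.a, 8)
        elif self.n_scheme == "unbalanced_np":
            base = np.array([8, 10, 13, 17, 20])[: self.a]
        else:
            base = np.array([20, 17, 13, 10, 8])[: self.a]
        return base + self.r

    def group_sigmas(self) -> np.ndarray:
        if self.variance == "homoscedastic":
            return np.ones(self.a)
        if self.variance == "groupwise":
            return np.concatenate([[self.sigma1], GROUPWISE_SIGMA_TAIL])[: self.a]
        raise ValueError("complete heteroscedasticity has no group sigmas")

    def effects(self) -> np.ndarray:
        b = np.full(self.a, BASELINE_EFFECT)
        if self.alternative == "alt1":
            b[0] -= self.delta
        elif self.alternative == "alt2":
            b[0] -= self.delta
            b[1] += self.delta
        return b


@dataclass
class SimResult:
    """Monte-Carlo rejection rates of one scenario."""

    rejection_rate: float
    mc_se: float
    per_contrast_rates: np.ndarray
    nsim: int
    n_failures: int
    config: SimConfig
    delta: float = 0.0


def _standardized_errors(dist: str, size, rng: np.random.Generator) -> np.ndarray:
    """Draws of (Z - EZ)/sd(Z) for the configured parent distribution."""
    if dist == "normal":
        return rng.standard_normal(size)
    if dist == "t5":
        return rng.standard_t(5, size) / np.sqrt(5.0 / 3.0)
    if dist == "chisq12":
        return (rng.chisquare(12, size) - 12.0) / np.sqrt(24.0)
    if dist == "exp1":
        return rng.exponential(1.0, size) - 1.0
    raise ValueError(f"unknown error distribution {dist!r}")


def generate_dataset(config: SimConfig, rng: np.random.Generator) -> AncovaData:
    """Generate one ANCOVA dataset from the configured scenario."""
    n = config.sample_sizes()
    N = int(n.sum())
    codes = np.repeat(np.arange(config.a), n)
    M = rng.normal(7.0, 1.0, size=(N, COVARIATE_EFFECTS.size))
    z = _standardized_errors(config.error_dist, N, rng)
    if config.variance == "complete":
        sigma = rng.uniform(0.5, 4.0, size=N)
    else:
        sigma = config.group_sigmas()[codes]
    b = config.effects()
    y = b[codes] + M @ COVARIATE_EFFECTS + sigma * z
    return AncovaData(y=y, groups=codes, covariates=M)


def _run_replicate(data: AncovaData, C: ContrastMatrix, config: SimConfig,
                   rng: np.random.Generator):
    """Test decisions (global, per contrast) for one generated dataset.

    The t-approximation path decides via the cdf of max|T| at each |T_l|,
    which is equivalent to comparing against the equicoordinate quantile but
    needs one rectangle probability per contrast instead of a root search.
    """
    if config.method == "boot":
        res = boot_mctp(data, C, alpha=config.alpha, nboot=config.nboot,
                        seed=int(rng.integers(2 ** 31)))
        return res.reject_global, res.reject
    fit = fit_ancova(data, mode="groupwise", estimator="gls_plugin")
    T, _ = test_statistics(fit, C)
    R = correlation_matrix(fit.Psi_hat, C)
    if config.method == "asymptotic":
        nu = np.inf
    else:
        rule = config.method.split("_", 1)[1]
        nu = select_df(box_df(fit, C), rule)
    p = np.array([1.0 - max_abs_cdf(abs(t), R, nu) for t in T])
    reject = p <= config.alpha
    return bool(reject.any()), reject


def _study(config: SimConfig) -> SimResult:
    C = build_contrast(config.contrast, config.a)
    seeds = np.random.SeedSequence(config.seed).spawn(config.nsim)
    n_global = 0
    per_contrast = np.zeros(C.q)
    n_failures = 0
    n_done = 0
    for ss in seeds:
        rng = np.random.default_rng(ss)
        try:
            data = generate_dataset(config, rng)
            rej_global, rej = _run_replicate(data, C, config, rng)
        except (ValueError, ArithmeticError, np.linalg.LinAlgError):
            n_failures += 1
            if n_failures > max(1, 0.01 * config.nsim):
                raise RuntimeError(
                    f"more than 1% of replicates failed ({n_failures} of "
                    f"{config.nsim}); scenario aborted"
                )
            continue
        n_done += 1
        n_global += rej_global
        per_contrast += rej
    rate = n_global / n_done if n_done else np.nan
    mc_se = float(np.sqrt(rate * (1.0 - rate) / n_done)) if n_done else np.nan
    return SimResult(
        rejection_rate=float(rate), mc_se=mc_se,
        per_contrast_rates=per_contrast / max(n_done, 1),
        nsim=n_done, n_failures=n_failures, config=config,
        delta=config.delta,
    )


def type1_study(config: SimConfig) -> SimResult:
    """Familywise type-I-error study under the null hypothesis."""
    if config.alternative != "null":
        raise ValueError("type1_study requires alternative='null'")
    return _study(config)


def power_study(config: SimConfig, delta_grid: Sequence[float]) -> List[SimResult]:
    """Power study over a grid of effect sizes delta (alt1 or alt2)."""
    if config.alternative not in ("alt1", "alt2"):
        raise ValueError("power_study requires alternative 'alt1' or 'alt2'")
    results = []
    for d in delta_grid:
        results.append(_study(replace(config, delta=float(d))))
    return results


def plot_rates(results: Sequence[SimResult], ax=None, label: Optional[str] = None):
    """Basic rejection-rate-versus-delta panel (requires matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    deltas = [r.delta for r in results]
    rates = [r.rejection_rate for r in results]
    ax.plot(deltas, rates, marker="o", label=label)
    ax.set_xlabel("effect size delta")
    ax.set_ylabel("rejection rate")
    if label:
        ax.legend()
    return ax
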