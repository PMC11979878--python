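"""Wild-bootstrap MCTP, valid under complete (subject-wise) heteroscedasticity.

The observed statistics use the OLS effect estimator and White's HC sandwich
covariance.  The reference distribution of ``T0 = max_l |T_l|`` is obtained by
resampling ``Y*_ij = eps_ij * W_ij * (1 - p_ij)^(-1/2)`` with Rademacher signs
``W_ij`` and leverage-scaled OLS residuals, recomputing the statistic on every
resample.  The correlation between the contrast statistics is never estimated:
it is carried implicitly by the joint resampling distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .contrasts import ContrastMatrix
from .model import AncovaData, DesignMatrices, fit_ancova


class LeverageError(ValueError):
    """A leverage of 1 makes the residual scaling undefined."""


@dataclass
class BootResult:
    """Result of the wild-bootstrap MCTP."""

    estimates: np.ndarray
    statistics: np.ndarray
    T0: float
    boot_draws: np.ndarray
    critical: float
    p_adjusted: np.ndarray
    sci: np.ndarray
    alpha: float
    nboot: int
    seed: Optional[int]
    reject: np.ndarray
    reject_global: bool
    row_labels: list
    n_degenerate: int


def _scaled_residuals(residuals: np.ndarray, hat_diag: np.ndarray) -> np.ndarray:
    residuals = np.asarray(residuals, dtype=float).ravel()
    hat_diag = np.asarray(hat_diag, dtype=float).ravel()
    if residuals.size != hat_diag.size:
        raise ValueError("residuals and hat_diag must have equal length")
    if np.any(hat_diag >= 1.0):
        raise LeverageError(
            "leverage p_ij >= 1: the wild-bootstrap residual scaling "
            "(1 - p_ij)^(-1/2) is undefined"
        )
    return residuals / np.sqrt(1.0 - hat_diag)


def wild_sample(residuals: np.ndarray, hat_diag: np.ndarray,
                rng: np.random.Generator) -> np.ndarray:
    """One wild resample ``Y* = eps * W * (1 - p)^{-1/2}`` with Rademacher
    signs drawn from ``rng``."""
    scaled = _scaled_residuals(residuals, hat_diag)
    signs = rng.integers(0, 2, size=scaled.size) * 2 - 1
    return scaled * signs


def boot_statistic(sample: np.ndarray, design: DesignMatrices,
                   C: ContrastMatrix) -> float:
    """Max contrast statistic ``T0* = max_l |c_l' b*| / sqrt(c_l' Psi* c_l)``
    of one resample, using OLS effects and the HC sandwich on the resample's
    own squared residuals.  A resample with zero contrast variance yields
    ``+inf`` (a conservative degenerate draw)."""
    sample = np.asarray(sample, dtype=float).ravel()
    G = np.linalg.pinv(design.B)            # (B'B)^-1 B'
    coef = G @ sample
    resid = sample - design.B @ coef
    V = C.C @ G[: design.n_groups]          # q x N rows c_l' PB (effect block)
    num = np.abs(C.C @ coef[: design.n_groups])
    den2 = (V ** 2) @ (resid ** 2)
    if np.any(den2 <= 0.0):
        return np.inf
    return float(np.max(num / np.sqrt(den2)))


def _critical_index(nboot: int, alpha: float) -> int:
    """0-based index of the order statistic serving as the bootstrap critical
    value: the ceil((1-alpha)(nboot+1))-th smallest draw.  With this choice
    ``p = (1 + #{T* >= T0})/(nboot + 1) <= alpha`` holds exactly iff
    ``T0 > critical`` (no ties), so p-values, rejections and SCIs are
    coherent."""
    k = int(np.floor(alpha * (nboot + 1) - 1.0 + 1e-9))  # max count with p <= alpha
    if k < 0:
        return nboot  # no draw count can reject; sentinel handled by caller
    return nboot - k - 1


def boot_mctp(data: AncovaData, C: ContrastMatrix, alpha: float = 0.05,
              nboot: int = 10000, seed: Optional[int] = None) -> BootResult:
    """Run the wild-bootstrap MCTP.

    Observed statistics come from the OLS fit with subject-wise (HC) variance;
    ``nboot`` Rademacher resamples of the leverage-scaled residuals provide the
    empirical distribution of the max statistic.  ``seed`` makes the run
    reproducible; p-values are ``(1 + #{T0* >= |T_l|}) / (nboot + 1)``.
    """
    if nboot < 100:
        raise ValueError("nboot must be at least 100")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie strictly between 0 and 1")
    if C.a != data.n_groups:
        raise ValueError(
            f"contrast matrix has {C.a} columns but the data has "
            f"{data.n_groups} cells"
        )
    rng = np.random.default_rng(seed)
    fit = fit_ancova(data, mode="subjectwise", estimator="ols")
    design = fit.design
    delta = C.C @ fit.b_hat
    var = np.einsum("ij,jk,ik->i", C.C, fit.Psi_hat, C.C)
    if np.any(var <= 0):
        raise ValueError("zero estimated variance for a contrast row")
    T = delta / np.sqrt(var)
    T0 = float(np.max(np.abs(T)))

    scaled = _scaled_residuals(fit.residuals, design.hat_diag)
    G = np.linalg.pinv(design.B)
    V = C.C @ G[: design.n_groups]

    n = design.n_obs
    draws = np.empty(nboot)
    chunk = max(1, min(nboot, int(4e6 // max(n, 1))))
    done = 0
    n_degenerate = 0
    while done < nboot:
        b = min(chunk, nboot - done)
        W = rng.integers(0, 2, size=(n, b)) * 2 - 1
        Ystar = scaled[:, None] * W
        coef = G @ Ystar
        resid = Ystar - design.B @ coef
        num = np.abs(V @ Ystar)
        den2 = (V ** 2) @ (resid ** 2)
        with np.errstate(divide="ignore", invalid="ignore"):
            Tstar = num / np.sqrt(den2)
        bad = ~np.all(den2 > 0.0, axis=0)
        vals = np.max(Tstar, axis=0)
        vals[bad] = np.inf
        n_degenerate += int(bad.sum())
        draws[done:done + b] = vals
        done += b

    sorted_draws = np.sort(draws)
    idx = _critical_index(nboot, alpha)
    critical = float(sorted_draws[idx]) if idx < nboot else np.inf
    p_adj = (1.0 + np.sum(draws[None, :] >= np.abs(T)[:, None], axis=1)) \
        / (nboot + 1.0)
    reject = p_adj <= alpha
    half = critical * np.sqrt(var)
    sci = np.column_stack([delta - half, delta + half])
    return BootResult(
        estimates=delta, statistics=T, T0=T0, boot_draws=draws,
        critical=critical, p_adjusted=p_adj, sci=sci, alpha=alpha,
        nboot=nboot, seed=seed, reject=reject,
        reject_global=bool(reject.any()), row_labels=list(C.row_labels),
        n_degenerate=n_degenerate,
    )
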