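"""Heteroscedastic ANCOVA model: design matrices, variance and effect estimators.

The model is ``Y = X b + M p + eps`` with ``X`` a block indicator matrix of the
``a`` treatment cells, ``M`` an ``N x m`` covariate matrix and independent
errors whose variances are either constant within each group (group-wise
heteroscedasticity, the Behrens-Fisher situation) or free to differ subject by
subject (complete heteroscedasticity).  Treatment effects and regression
coefficients are estimated by (generalized) least squares; their covariances
are sandwich forms ``D Sigma D'`` and ``A Sigma A'`` built from the generating
matrices of the weighted normal equations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.linalg


class DesignRankError(ValueError):
    """The stacked design (X, M) is rank deficient."""


class DegreesOfFreedomError(ValueError):
    """A group has too few subjects for its variance estimator."""


@dataclass
class AncovaData:
    """Long-format ANCOVA data: one response, one cell label and m covariates
    per subject.

    Parameters
    ----------
    y : array-like, shape (N,)
        Numeric response.
    groups : array-like, shape (N,)
        Cell label per subject.  Cells are ordered by first appearance unless
        ``group_order`` fixes an explicit ordering (used by two-way layouts,
        where cells are ordered first-factor slow).
    covariates : array-like, shape (N, m), optional
        Numeric covariates; ``m = 0`` reduces the model to a heteroscedastic
        ANOVA.
    factor_structure : tuple of int, optional
        Level counts of the crossed factors when the cells arise from a
        higher-way layout (e.g. ``(2, 6)``); purely descriptive.
    """

    y: np.ndarray
    groups: np.ndarray
    covariates: Optional[np.ndarray] = None
    factor_structure: Optional[tuple] = None
    group_order: Optional[Sequence] = None

    group_labels: np.ndarray = field(init=False)
    group_codes: np.ndarray = field(init=False)
    group_sizes: np.ndarray = field(init=False)

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float).ravel()
        n = self.y.size
        self.groups = np.asarray(self.groups).ravel()
        if self.groups.size != n:
            raise ValueError(
                f"groups has length {self.groups.size}, expected {n}"
            )
        if self.covariates is None:
            self.covariates = np.empty((n, 0))
        self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
        if self.covariates.shape[0] != n:
            self.covariates = self.covariates.T
        if self.covariates.shape[0] != n:
            raise ValueError("covariate matrix does not match the response length")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("response contains non-finite values")
        if not np.all(np.isfinite(self.covariates)):
            raise ValueError("covariate matrix contains missing/non-finite values")

        if self.group_order is None:
            # order of first appearance
            _, idx = np.unique(self.groups, return_index=True)
            labels = self.groups[np.sort(idx)]
        else:
            labels = np.asarray(self.group_order)
            if set(labels.tolist()) != set(np.unique(self.groups).tolist()):
                raise ValueError("group_order does not match the observed labels")
        self.group_labels = labels
        lookup = {lab: i for i, lab in enumerate(labels.tolist())}
        self.group_codes = np.array([lookup[g] for g in self.groups.tolist()])
        self.group_sizes = np.bincount(self.group_codes, minlength=len(labels))
        if np.any(self.group_sizes < 1):
            raise ValueError("every cell must contain at least one subject")

    @property
    def n_obs(self) -> int:
        return self.y.size

    @property
    def n_groups(self) -> int:
        return len(self.group_labels)

    @property
    def n_covariates(self) -> int:
        return self.covariates.shape[1]


@dataclass
class DesignMatrices:
    """Design and projection matrices of a fitted layout.

    ``X`` is the ``N x a`` block indicator matrix, ``P = X(X'X)^{-1}X'`` the
    projection on the group space, ``Q = I - P`` its complement, ``B = (X, M)``
    the stacked design, and ``hat_diag`` the leverages (diagonal of the hat
    matrix of ``B``).
    """

    X: np.ndarray
    M: np.ndarray
    B: np.ndarray
    P: np.ndarray
    Q: np.ndarray
    hat_diag: np.ndarray
    group_codes: np.ndarray
    group_sizes: np.ndarray

    @property
    def n_obs(self) -> int:
        return self.B.shape[0]

    @property
    def n_groups(self) -> int:
        return self.X.shape[1]

    @property
    def n_covariates(self) -> int:
        return self.M.shape[1]


@dataclass
class VarianceEstimate:
    """Diagonal error-covariance estimate.

    ``mode='groupwise'`` carries the unbiased per-group estimators
    ``sigma2_i = Y_i' Q_i Y_i / (n_i - 1 - rank(M_i))`` expanded to the
    subject level; ``mode='subjectwise'`` carries White's HC estimator, the
    squared OLS residuals.
    """

    mode: str
    diag: np.ndarray
    group_sigma2: Optional[np.ndarray] = None
    group_df: Optional[np.ndarray] = None


@dataclass
class FitResult:
    """Estimated treatment effects and regression coefficients with sandwich
    covariances."""

    b_hat: np.ndarray
    p_hat: np.ndarray
    Psi_hat: np.ndarray
    Xi_hat: np.ndarray
    residuals: np.ndarray
    variance: VarianceEstimate
    estimator: str
    design: DesignMatrices
    D: np.ndarray
    A: np.ndarray
    group_labels: np.ndarray


def _numerical_rank(mat: np.ndarray) -> int:
    """Numerical rank with the standard tolerance rule
    ``max(shape) * eps * sigma_max``."""
    if mat.size == 0:
        return 0
    s = np.linalg.svd(mat, compute_uv=False)
    if s.size == 0 or s[0] == 0.0:
        return 0
    tol = max(mat.shape) * np.finfo(float).eps * s[0]
    return int(np.sum(s > tol))


def build_design(data: AncovaData) -> DesignMatrices:
    """Build the design, projection and hat matrices for an ANCOVA layout.

    Raises
    ------
    DesignRankError
        If the stacked design ``B = (X, M)`` is rank deficient (e.g. a
        covariate collinear with the group indicators).
    """
    n = data.n_obs
    a = data.n_groups
    X = np.zeros((n, a))
    X[np.arange(n), data.group_codes] = 1.0
    M = data.covariates
    B = np.hstack([X, M])

    rank = _numerical_rank(B)
    if rank < B.shape[1]:
        # name offending columns via pivoted QR
        _, r, piv = scipy.linalg.qr(B, pivoting=True, mode="economic")
        d = np.abs(np.diag(r))
        tol = max(B.shape) * np.finfo(float).eps * (d[0] if d.size else 0.0)
        bad = sorted(piv[np.where(d <= tol)[0]].tolist())
        names = [
            f"group[{data.group_labels[j]}]" if j < a else f"covariate[{j - a}]"
            for j in bad
        ]
        raise DesignRankError(
            f"design matrix (X, M) is rank deficient (rank {rank} < "
            f"{B.shape[1]}); offending columns: {', '.join(names)}"
        )

    # P is block diagonal with J_{n_i}/n_i blocks; computed via the indicator
    inv_sizes = 1.0 / data.group_sizes
    P = (X * inv_sizes) @ X.T
    Q = np.eye(n) - P
    qb, _ = np.linalg.qr(B)
    hat_diag = np.einsum("ij,ij->i", qb, qb)
    return DesignMatrices(
        X=X, M=M, B=B, P=P, Q=Q, hat_diag=hat_diag,
        group_codes=data.group_codes, group_sizes=data.group_sizes,
    )


def estimate_sigma_groupwise(data: AncovaData, design: DesignMatrices) -> VarianceEstimate:
    """Unbiased group-wise variance estimators.

    For each group ``i`` the response is regressed on an intercept and the
    group-specific covariate block ``M_i``; the residual sum of squares is
    divided by ``n_i - 1 - rank(M_i)``.

    Raises
    ------
    DegreesOfFreedomError
        If some group has ``n_i - 1 - rank(M_i) < 1``.
    """
    a = data.n_groups
    sigma2 = np.empty(a)
    group_df = np.empty(a)
    diag = np.empty(data.n_obs)
    for i in range(a):
        mask = data.group_codes == i
        yi = data.y[mask]
        mi = data.covariates[mask]
        ni = yi.size
        rank_mi = _numerical_rank(mi)
        df = ni - 1 - rank_mi
        if df < 1:
            raise DegreesOfFreedomError(
                f"group '{data.group_labels[i]}' has n_i - 1 - rank(M_i) = "
                f"{df} <= 0; the group-wise variance estimator is undefined"
            )
        bi = np.hstack([np.ones((ni, 1)), mi])
        coef, *_ = np.linalg.lstsq(bi, yi, rcond=None)
        resid = yi - bi @ coef
        ss = float(resid @ resid)
        if ss < -1e-10:
            raise ArithmeticError("negative residual quadratic form")
        sigma2[i] = max(ss, 0.0) / df
        group_df[i] = df
        diag[mask] = sigma2[i]
    return VarianceEstimate(mode="groupwise", diag=diag,
                            group_sigma2=sigma2, group_df=group_df)


def estimate_sigma_subjectwise(residuals: np.ndarray, design: DesignMatrices) -> VarianceEstimate:
    """White's heteroscedasticity-consistent estimator: squared OLS residuals."""
    residuals = np.asarray(residuals, dtype=float).ravel()
    if residuals.size != design.n_obs:
        raise ValueError(
            f"residual vector has length {residuals.size}, design has "
            f"{design.n_obs} subjects"
        )
    return VarianceEstimate(mode="subjectwise", diag=residuals ** 2)


def generating_matrices(design: DesignMatrices,
                        variance: Optional[VarianceEstimate] = None):
    """Generating matrices ``(A, D)`` of the (weighted) normal equations.

    ``p_hat = A Y`` and ``b_hat = D Y``.  ``variance=None`` requests identity
    weights (OLS).  ``Q`` is the unweighted complement projection throughout.

    Raises
    ------
    np.linalg.LinAlgError
        If ``M' Q Sigma^{-1} M`` is singular (collinear covariates).
    """
    n = design.n_obs
    a = design.n_groups
    m = design.n_covariates
    if variance is None:
        w = np.ones(n)
    else:
        w = 1.0 / np.asarray(variance.diag, dtype=float)
        if not np.all(np.isfinite(w)) or np.any(variance.diag <= 0):
            raise ValueError(
                "GLS plug-in weights require a strictly positive variance diagonal"
            )

    # (X' Sigma^-1 X)^-1 X' Sigma^-1 : weighted group averaging operator
    group_w = np.bincount(design.group_codes, weights=w, minlength=a)
    D0 = np.zeros((a, n))
    D0[design.group_codes, np.arange(n)] = w / group_w[design.group_codes]

    if m == 0:
        return np.empty((0, n)), D0

    MQ = design.M.T @ design.Q          # M' Q
    MQw = MQ * w                        # M' Q Sigma^-1
    S = MQw @ design.M                  # M' Q Sigma^-1 M
    try:
        c, low = scipy.linalg.cho_factor(0.5 * (S + S.T))
        A = scipy.linalg.cho_solve((c, low), MQw)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "M' Q Sigma^-1 M is singular: covariates are collinear"
        ) from exc
    D = D0 - (D0 @ design.M) @ A
    return A, D


def fit_ancova(data: AncovaData, mode: str = "groupwise",
               estimator: Optional[str] = None) -> FitResult:
    """Fit the heteroscedastic ANCOVA and return effects, coefficients and
    sandwich covariances.

    The fit is a two-pass procedure: an OLS pass provides residuals, the
    variance is then estimated per ``mode`` (``'groupwise'`` from the raw
    per-group regressions, ``'subjectwise'`` by squaring the OLS residuals),
    and for ``estimator='gls_plugin'`` the effects are re-estimated with the
    estimated variance plugged into the generating matrices.  The default
    pairing is groupwise -> gls_plugin and subjectwise -> ols.
    """
    if mode not in ("groupwise", "subjectwise"):
        raise ValueError(f"unknown variance mode {mode!r}")
    if estimator is None:
        estimator = "gls_plugin" if mode == "groupwise" else "ols"
    if estimator not in ("gls_plugin", "ols"):
        raise ValueError(f"unknown estimator {estimator!r}")

    design = build_design(data)
    A0, D0 = generating_matrices(design, None)
    b0 = D0 @ data.y
    p0 = A0 @ data.y
    resid0 = data.y - design.X @ b0 - design.M @ p0

    if mode == "groupwise":
        variance = estimate_sigma_groupwise(data, design)
    else:
        variance = estimate_sigma_subjectwise(resid0, design)

    if estimator == "gls_plugin":
        A, D = generating_matrices(design, variance)
        b_hat = D @ data.y
        p_hat = A @ data.y
        residuals = data.y - design.X @ b_hat - design.M @ p_hat
    else:
        A, D = A0, D0
        b_hat, p_hat, residuals = b0, p0, resid0

    Psi_hat = (D * variance.diag) @ D.T
    Xi_hat = (A * variance.diag) @ A.T
    Psi_hat = 0.5 * (Psi_hat + Psi_hat.T)
    Xi_hat = 0.5 * (Xi_hat + Xi_hat.T)
    return FitResult(
        b_hat=b_hat, p_hat=p_hat, Psi_hat=Psi_hat, Xi_hat=Xi_hat,
        residuals=residuals, variance=variance, estimator=estimator,
        design=design, D=D, A=A, group_labels=data.group_labels,
    )
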