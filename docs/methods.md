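# Methods

## Model and estimators

`hetmctp` fits the heteroscedastic ANCOVA `Y = Xb + Mp + ε` for `a`
treatment cells and `m` covariates.  Two variance structures are supported:

* **group-wise** (`Σ_G = ⊕ σ_i² I_{n_i}`): each cell has its own error
  variance — the Behrens–Fisher situation typical of pre-clinical trials;
* **subject-wise** (`Σ_I = diag(σ_ij²)`): complete heteroscedasticity, as in
  observational data.

Estimation is a two-pass procedure.  An OLS pass provides residuals; the
variance is then estimated (group-wise: per-cell regressions of `Y_i` on
`(1, M_i)` with denominator `n_i − 1 − rank(M_i)`; subject-wise: squared OLS
residuals); and, for the group-wise model, the effects are re-estimated by
plugging `Σ̂_G` into the generating matrices

    A = (M'QΣ⁻¹M)⁻¹ M'QΣ⁻¹,
    D = (X'Σ⁻¹X)⁻¹X'Σ⁻¹ − (X'Σ⁻¹X)⁻¹X'Σ⁻¹ M A,

so that `b̂ = DY`, `p̂ = AY`, `Ψ̂ = DΣ̂D'`, `Ξ̂ = AΣ̂A'`.  The subject-wise
route keeps the OLS point estimates (the HC sandwich then matches the
resampling scheme of the bootstrap).  Note that `Q = I − X(X'X)⁻¹X'` is the
*unweighted* complement projection in both displays; with `Σ = I` this gives
the exact unbiasedness identities `DX = I`, `DM = 0`, `AX = 0`, which the
test suite verifies numerically.  For general `Σ` the plug-in estimator is
consistent but not the exact GLS solution; we implement the printed form
deliberately and verify the identities at `Σ = I` only.

Linear systems are solved by Cholesky/QR factorizations, never by explicit
inversion.  `rank(M_i)` is the numerical rank with the standard tolerance
`max(shape) · eps · σ_max`.  A cell with `n_i − 1 − rank(M_i) < 1` is a hard
error: the unbiased variance estimator is undefined there, and silently
pooling variances would change the method.  Cells are ordered by first
appearance (one-way) or first-factor-slow (two-way), and the same convention
is shared by the table reader and the factorial contrast builder.

## Degrees of freedom

Each contrast variance `c_l'Ψ̂c_l = Σ_i s_{l,i} σ̂_i²` (with
`s_{l,i}` the within-cell-i sum of squared entries of `c_l'D`) is matched in
its first two moments to a scaled chi-square, giving

    ν_l = (c_l'Ψ̂c_l)² / Σ_i s_{l,i}² σ̂_i⁴ / (n_i − 1 − rank(M_i)).

In the two-sample, no-covariate limit this is exactly the Welch–Satterthwaite
formula, which is the criterion we used to fix the reading of the df display
(its printed form does not parse literally).  The q candidates are collapsed
by a selection rule: `min` (most conservative), `max`, or `mean` rounded to
the nearest integer (rounding attaches only to the mean rule; min/max stay
real-valued).  The default is `mean`; `asymptotic` skips the approximation
and uses the multivariate normal reference.

## Equicoordinate quantiles and p-values

Critical values solve `P(max_l |T_l| ≤ t) = 1 − α` under the central
multivariate `t(ν, R̂)`; adjusted p-values are `1 − P(max ≤ |T_l|)`.  The
rectangle probabilities are computed by randomized quasi-Monte-Carlo (Genz)
integration through scipy with a fixed internal seed, so all outputs are
bit-reproducible; the root is bracketed between the unadjusted and the
Bonferroni two-sided univariate quantile.  `q = 1` short-circuits to exact
univariate quantiles.

The grand-mean family keeps all `a` (linearly dependent) rows, so `R̂` is
singular.  The singular multivariate-normal rectangle goes through scipy's
degenerate-covariance path, which we validated against plain Monte Carlo.
scipy's multivariate-*t* CDF, however, mishandles rank-deficient shape
matrices (verified against a 4×10⁶-draw Monte-Carlo oracle), so singular
`R̂` with finite ν uses an internal integration: with `R = LL'` (rank-r
eigenfactor) and `T = Lu/s`, `s² = χ²_ν/ν`, the chi-square dimension is
integrated analytically — `P(max|T| ≤ t | u) = P(χ²_ν ≥ ν(max|Lu|/t)²)` — and
the smooth r-dimensional remainder is averaged over a scrambled Sobol net
(2¹⁵ points, fixed seed).  Agreement with the Monte-Carlo oracle is ≲ 4·10⁻⁴
in probability, within the 5·10⁻⁴ integration contract.

Decisions are taken from a single primitive to make them coherent:
`reject_l ⇔ |T_l| ≥ critical`, the global rejection is their disjunction
(equivalently `T0 ≥ critical`), and SCIs use the same critical value, so
interval zero-exclusion coincides with rejection exactly.  Adjusted p-values
are computed by the same integration, so `min_l p_l ≤ α` agrees with the
global decision up to the integration tolerance (a ~10⁻³ knife edge around
`p = α`, acknowledged in the tests).

## Wild bootstrap

Under complete heteroscedasticity the max statistic's distribution is
approximated conditionally on the data by `nboot` resamples
`Y*_ij = ε̂_ij W_ij (1 − p_ij)^{−1/2}` (Rademacher `W`, leverages `p_ij` of
the full design `B = (X, M)`, computed once).  Each resample's statistic uses
the OLS effects and the HC sandwich of its own squared residuals.  Defaults:
`nboot = 10000`; a seed is required for reproducibility in practice.

Conventions chosen where the method leaves freedom:

* p-values are `(1 + #{T0* ≥ |T_l|}) / (nboot + 1)` — never exactly zero;
* the critical value is the `⌈(1−α)(nboot+1)⌉`-th order statistic of the
  draws.  With this (and only this) quantile convention the p-value rule,
  the critical-value rule and SCI zero-exclusion are *exactly* equivalent
  (up to ties of probability ~2^{1−N}), which is why it is preferred over
  interpolated quantile definitions;
* a resample with zero contrast variance counts as `+∞` (conservative)
  rather than being dropped, keeping `nboot` fixed.

## Simulation engine

`generate_dataset` reproduces the stated data-generating process:
`Y_ik = b_i + M_ik'p + σ_ik (Z_ik − EZ)/sd(Z)` with `m = 4` covariates from
N(7, 1), `p = (0.2, 1, 1.5, 2)'`, baseline `b_i = 7`; errors from N(0,1),
t₅, χ²₁₂ or Exp(1), standardized analytically; variances homoscedastic
(σ = 1), group-wise (σ = (σ₁, 1.5, 1, 0.5, 0.75) truncated to `a` cells,
σ₁ ∈ {2, 4, 6}) or subject-wise U(0.5, 4).  Sample sizes are
(8, …, 8) + r balanced, or (8, 10, 13, 17, 20) + r / reversed for
negative/positive pairing.  Alternatives shift the first cell by −δ (alt1)
and additionally the second by +δ (alt2), δ ∈ [0, 2].

Covariates are redrawn every replicate (the unconditional reading of the
generator).  Per-replicate seeds are spawned deterministically from the
master seed, so results are independent of any parallel execution order.
The type-I/power drivers decide each replicate by comparing adjusted
p-values with α (one rectangle probability per contrast) rather than
root-finding the critical value — the decisions are identical, the runtime
is ~10× lower.  Replicate failures (e.g. degenerate df) are counted and more
than 1% aborts the study; none occur in the shipped scenarios.

What a green simulation test establishes: rejection behaviour of the
procedures under the stated parametric world (independent errors, linear
covariate effects, cells of moderate size).  It does not establish behaviour
under model misspecification beyond the variance structure, dependent
errors, covariate–treatment interactions, or missing data, none of which the
generator emulates.

## Defaults and tunables

| parameter | default | meaning |
|---|---|---|
| `df_rule` | `mean` | central candidate; min is most conservative, max most liberal |
| `alpha` | 0.05 | two-sided familywise level |
| `nboot` | 10000 | bootstrap resamples |
| `nsim` | 5000 (t) / 1000×1000 (boot) | desk-scale study sizes; the full grid used 10000×10000 |
| integration tolerance | 5·10⁻⁴ | on rectangle probabilities; quantile root tolerance 10⁻⁶ |

## Known limitations

* Tests are two-sided only; one-sided variants are out of scope.
* The multivariate-t route requires the group-wise variance estimator; under
  complete heteroscedasticity it remains usable (and is exercised in the
  simulations) but the bootstrap is the method of choice there.
* Skewed error distributions with grand-mean contrasts leave a small-sample
  liberality that only decays slowly with `n` — the simulation engine
  reproduces the documented ≈8% level for five exponential groups of 40.
* The bootstrap is costlier than the t-approximation by a factor ~`nboot`.
* Printed σ/sample-size vectors cover `a ≤ 5` cells in the simulation
  configs (truncation is the only consistent reading); the analysis code
  itself has no such limit.
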