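# Methods

## Model

Each of k ordinal items with m categories is a discretization of a latent
standard-normal score: `X_i = x ⇔ τ_{x-1} < X_i* ≤ τ_x`, with τ_0 = −∞ and
τ_m = +∞, so an item contributes m − 1 free cut-points. The latent vector is
multivariate normal with unit variances (the identification convention used
throughout: zero mean, unit variance, thresholds free — the alternative of
fixing two thresholds is impossible for dichotomous items and is not
implemented). A confirmatory factor model constrains the latent correlation
matrix to ΛΦΛ′ off the diagonal, where Λ is a k×q loading pattern and Φ a
factor correlation matrix with unit diagonal; residual variances
Θ = I − diag(ΛΦΛ′) must be positive, so communalities must stay below one.
The *baseline* model drops the factor structure and parameterizes all
k(k−1)/2 latent (polychoric) correlations directly — its fit is a test of
the underlying-normality assumption itself.

## Estimation

The pairwise maximum likelihood (PML) objective is the sum over all item
pairs of bivariate multinomial log-likelihoods, with cell probabilities
given by standard-bivariate-normal rectangles between consecutive
thresholds. The multinomial constant is dropped for every model alike, so
objective differences are unaffected. Estimation is one-step: thresholds
and structural parameters are maximized jointly.

Numerics:

* **Bivariate kernel.** Rectangle probabilities are assembled from a
  vectorized implementation of Genz's bivariate-normal CDF algorithm
  (Gauss–Legendre in arcsin ρ for |ρ| < 0.925, the near-singular expansion
  beyond), accurate to ~1e-14 and checked against scipy's multivariate
  normal in the tests.
* **Analytic gradients.** ∂Φ₂/∂ρ is the bivariate density (Plackett's
  identity) and ∂Φ₂/∂x = φ(x)·Φ((y−ρx)/√(1−ρ²)); these are chained through
  the factor structure (∂ℓ/∂Λ = MΛΦ, ∂ℓ/∂Φ = Λ′MΛ for the matrix M of
  pair-level gradients) and the parameter transforms. Finite-difference
  agreement is part of the test suite.
* **Transforms and bounds.** Thresholds are coded as first threshold plus
  log-gaps, which makes within-item ordering automatic; correlation-type
  parameters (baseline polychorics, factor correlations) pass through
  atanh; loadings are unconstrained within ±3. L-BFGS-B with projected
  gradient tolerance 1e-6 does the maximization. Implied pair correlations
  from factor structures are passed through a squash that is exactly the
  identity on [−0.999, 0.999] and asymptotes inside (−1, 1), so line
  searches cannot leave the domain and the gradient stays consistent with
  the value.
* **Starting values.** Thresholds from the inverse normal of cumulative
  marginal proportions; baseline correlations from a coarse two-step
  polychoric search per pair; loadings 0.5 and factor correlations 0.25.
  Cheap, interior, and robust across the study's conditions.
* **Degenerate data.** Cell probabilities are floored at 1e-12 inside
  logarithms (flagged when an observed cell hits the floor). An item with
  an empty observed category gets its threshold start pinned near the ±6
  bound and the fit is flagged rather than rejected: such samples are
  retained because redrawing them would bias rejection rates. Heywood
  solutions (communality ≥ 1) are reported as estimated and flagged, never
  truncated, so dispersion summaries are not artificially deflated.
  Non-convergence is reported on the returned fit, not raised.

## Full-pattern probabilities

`C_F` and `C_M` need all m^k model-implied pattern probabilities. Two routes:

* **Factor models** are conditionally independent given the q factors, so a
  pattern probability is a q-dimensional integral of products of univariate
  interval probabilities. Tensor-product Gauss–Hermite quadrature (48 nodes
  per factor dimension) evaluates the whole table at once to near machine
  precision; the table mass is exactly one by construction.
* **The baseline model** has an unstructured correlation matrix, handled by
  a randomized quasi-Monte Carlo rectangle integrator (Genz's sequential
  conditioning, 8 scrambled Sobol streams with a fixed internal seed so a
  given fit always yields the same statistic). Points are doubled until the
  randomized-QMC standard error per pattern drops below an absolute
  tolerance — 1e-6 by default; the Monte Carlo harness uses 1e-5, where the
  induced error in a C_F value at N=1000 is below 0.2 on statistics whose
  replication SDs are 20–40.

Tables are renormalized to unit mass before entering likelihood ratios
(the raw mass is retained for diagnostics) because per-pattern integration
error otherwise biases the ratio. Enumeration refuses above a configurable
ceiling (2·10⁵ patterns) instead of silently crawling.

## Fit statistics

* `C_F = 2N Σ_r p_r ln(p_r/π̂_r)`, summed over observed patterns only;
  df_F = m^k − n − 1 or df_F* = u_r − n − 1 (clamped at 1 with a flag when
  nonpositive, which can happen at N=200 with m=4). π̂ always comes from
  the model's *own* PML estimates.
* `C_M = C_F1 − C_F0` against the baseline, df_M = k(k−1)/2 + k(m−1) − n₁
  with n₁ counting all parameters of the model of interest including
  thresholds. Negative values — possible because PML estimates do not
  maximize the full-pattern likelihood — are reported as-is with p = 1 and
  a flag, never clamped, so calibration is unaffected.
* `C_P`: per pair `2N Σ p ln(p/π̂)` with df_P = m² − 2m; the overall
  statistic is the maximum over the k(k−1)/2 pairs, tested at
  α* = 2α/(k(k−1)). Ties (measure-zero) resolve to the lexicographically
  first pair; the decision depends only on the maximum value. For m = 2,
  df_P = 0 and the statistic is refused: a 2×2 table with two thresholds
  and one correlation is saturated, so underlying bivariate normality
  cannot be tested.
* All p-values are upper-tail chi-square; nothing is two-sided.

## Synthetic data and the Monte Carlo harness

The generator draws latent scores from N(0, Σ) by Cholesky factorization
and discretizes at fixed thresholds: {0} for m=2 (expected proportions
.50/.50), {−0.6, 0.6} for m=3 (.27/.45/.27), {−1.2, 0, 1.2} for m=4
(.11/.39/.39/.11). A latent score exactly at a cut-point goes to the lower
category. The population model has two correlated factors (Φ₁₂ = 0.5):
items 1–4 load 0.9, 0.8, 0.7, 0.5 on factor 1 and items 4–6 load 0.6, 0.7,
0.8 on factor 2, item 4 cross-loading. This 7-loading pattern is the unique
reading of the design consistent with both the difference-in-parameters
degrees of freedom (df_M = 7 for the two-factor model) and positive
residual variances; placing the cross-loading on item 3 instead would give
that item a communality of 1.09 and is therefore not a valid factor model.

Replication r of a condition uses generator seed `base_seed + r`; the
latent draw depends only on the seed and N, so the same continuous scores
underlie the m = 2, 3, 4 versions of a replication — one draw, three
discretizations. Two runs of a design are byte-identical. Non-converged
fits are flagged and counted; their statistics enter the aggregates when
computable, and the reported `n_used` states the denominator.

What the generator does *not* emulate: non-normal latent scores, unequal
category counts across items, missing data, and respondent-level
clustering. Passing tests therefore demonstrate calibration and power
*under the underlying-normal data-generating process*, not robustness to
its violation.

## Scale of the shipped experiments

The full design (9 conditions × 1000 replications × 3 fitted models, with
full-pattern statistics up to 4096 patterns) is a cluster-profile run,
available via `pmlfa study --profile full`. The test suite and the
acceptance script use desk-scale surrogates chosen so each quantity's
Monte Carlo standard error is small relative to the effect being checked:
500 replications for the C_P null mean and type-I error (SE of the mean
≈ 0.13), 300 for C_P power at N=200 (SE ≈ 2.7 points), 200 for C_M power
at N=1000 (where every replication rejects by a wide margin), and 100 per
condition for the loading-dispersion summary. Tolerances in the tests are
3 Monte Carlo standard errors of the scaled-down run.

## Known limitations

* No standard errors for PML estimates (sandwich/Godambe information is
  not implemented), and no residual-based composite-likelihood statistics.
* No weighted-least-squares estimator; the package covers the PML side
  only.
* `C_F`/`C_M` are limited by the pattern-enumeration ceiling; for large
  m^k the full-pattern machinery refuses by design, mirroring the
  sparseness problem that motivates `C_M` and `C_P` in the first place.
* The grand-average loading-estimate SD reproduces at ~0.046–0.048 where
  the original study reports 0.052; power and calibration quantities
  reproduce within Monte Carlo error, so the residual gap most likely
  reflects extra estimate dispersion in the original study's optimizer
  and its (unreported) handling of degenerate replications.
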