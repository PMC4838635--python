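# pmlfa — pairwise maximum likelihood factor analysis of ordinal data

Questionnaire and test items are usually scored on discrete ordinal scales.
The standard factor-analysis treatment assumes each observed code `x_i ∈
{1..m}` is a coarsened view of a latent continuous score `x_i*`, with the
vector of latent scores multivariate normal: `X_i = x ⇔ τ_{x-1} < X_i* ≤ τ_x`.
Full-information maximum likelihood for this model needs k-dimensional
normal integrals per response pattern and is infeasible beyond a handful of
items. **Pairwise maximum likelihood (PML)** replaces the full likelihood
with the sum of all bivariate log-likelihoods,

    ln L(ρ, τ) = Σ_{i<j} Σ_{x_i} Σ_{x_j} p_{x_i x_j} ln π_{x_i x_j}(ρ_ij, τ_i, τ_j),

where `p` are observed two-way proportions and `π` are bivariate-normal
rectangle probabilities, and maximizes it in a single step over thresholds
and structural parameters (loadings Λ, factor correlations Φ, with implied
correlations ΛΦΛ′ and residual variances Θ = I − diag(ΛΦΛ′)).

`pmlfa` implements, for analysts of ordinal scale data and for
methodologists studying composite-likelihood inference:

* the PML estimator with analytic gradients, for saturated ("baseline",
  all polychoric correlations free) and confirmatory factor models;
* three overall goodness-of-fit statistics with chi-square reference
  distributions:
  * `C_F = 2N Σ_r p_r ln(p_r/π̂_r)` over full response patterns,
    `df_F = m^k − n − 1` (or `df_F* = u_r − n − 1` on observed patterns);
  * `C_M = C_F(model) − C_F(baseline)`, testing the structural
    restrictions given underlying normality,
    `df_M = k(k−1)/2 + k(m−1) − n₁`;
  * `C_P = max_{i<j} C_P_ij`, the largest bivariate likelihood-ratio
    statistic, `df_P = m² − 2m`, tested at the Bonferroni level
    `α* = 2α/(k(k−1))` (undefined for dichotomous items);
* a synthetic-data generator for the two-factor population model used in
  the calibration/power study, and a Monte Carlo harness that reproduces
  its rejection-rate tables.

## Worked example

```python
import numpy as np
from pmlfa import (GenerationConfig, generate, study_model, fit_pml,
                   compute_cp)

ds = generate(GenerationConfig(n=500, m=3, seed=11))   # two-factor population
spec = study_model("two_factor", k=6, m=3)
fit = fit_pml(ds, spec)
print(np.round(fit.loadings_hat[spec.loading_mask], 3))
print(round(fit.phi_hat[0, 1], 3))
cp = compute_cp(ds.pairwise_tables, fit)
print(round(cp.statistic.value, 2), cp.df, cp.statistic.reject)
```

prints

```
[0.899 0.772 0.724 0.417 0.703 0.644 0.789]
0.476
8.66 3 False
```

— the seven loading estimates sit near the generating values
(0.9, 0.8, 0.7, 0.5, 0.6, 0.7, 0.8), the factor correlation near 0.5, and
the overall `C_P` of 8.66 on 3 df is below the Bonferroni critical value
(χ²₃ at α* = 0.05/15, about 13.7), so the correctly specified model is
(rightly) not rejected.

The same analysis from the shell:

```sh
pmlfa simulate config.yaml -o data.csv     # config: {n: 500, m: 3, seed: 11}
pmlfa fit data.csv model.yaml              # model: {k: 6, m: 3, model_id: two_factor}
pmlfa gof data.csv model.yaml              # C_F, C_M, C_P report as JSON
pmlfa study --profile desk -o results/     # the Monte Carlo tables
```

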