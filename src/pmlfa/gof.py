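"""Goodness-of-fit statistics for PML-estimated ordinal factor models.

Three likelihood-ratio-type statistics, all referred to upper-tail
chi-square distributions:

* ``C_F`` compares observed full-pattern proportions with the model-implied
  pattern probabilities evaluated at the PML estimates;
  df = m^k - n - 1, or alternatively u_r - n - 1 with u_r the number of
  *observed* patterns.
* ``C_M = C_F(model) - C_F(baseline)`` tests the structural restrictions
  given underlying multivariate normality; df is the parameter-count
  difference between the baseline and the model of interest.
* ``C_P`` is the maximum over all item pairs of the bivariate
  likelihood-ratio statistics, tested at a Bonferroni-adjusted level
  alpha* = 2 alpha / (k (k - 1)); undefined for dichotomous items, whose
  bivariate tables have df = m^2 - 2m = 0.

The model-implied probabilities entering each statistic come from that
model's *own* PML estimates (thresholds plus implied correlations), which
is what makes ``C_F`` model-specific.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.stats import chi2

from .models import FactorModelSpec
from .patterns import PatternProbabilities, all_pattern_probs, factor_pattern_probs
from .pml import PMLFit, cell_prob_table

__all__ = [
    "FitStatistic",
    "CPResult",
    "chisq_pvalue",
    "fitted_pattern_probs",
    "compute_cf",
    "compute_cm",
    "compute_cp",
    "bonferroni_alpha",
]

_CF_FLOOR = 1e-12


@dataclass(frozen=True)
class FitStatistic:
    """One statistic with its reference distribution and decision."""

    name: str                  # CF, CF_star, CM or CP
    value: float
    df: int
    p_value: float
    alpha_used: float
    reject: bool
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class CPResult:
    """All pairwise statistics plus the overall max-rule decision."""

    pair_stats: dict[tuple[int, int], float]
    df: int
    alpha: float
    alpha_star: float
    max_pair: tuple[int, int]
    statistic: FitStatistic = field(repr=False)


def chisq_pvalue(value: float, df: int) -> float:
    """Upper-tail chi-square probability; negative values map to p = 1."""
    if df < 1:
        raise ValueError("df must be at least 1")
    if value < 0:
        return 1.0
    return float(chi2.sf(value, df))


def bonferroni_alpha(alpha: float, k: int) -> float:
    """Family-wise adjusted level alpha* = 2 alpha / (k (k - 1))."""
    return 2.0 * alpha / (k * (k - 1))


def fitted_pattern_probs(fit: PMLFit, tol: float = 1e-6,
                         n_nodes: int = 48) -> PatternProbabilities:
    """Model-implied full-pattern table at a fit's PML estimates.

    Factor models go through the conditional-independence Gauss–Hermite
    route; the baseline (and any Heywood-case factor fit) through the
    quasi-Monte Carlo rectangle integrator on the implied correlations.
    """
    spec = fit.spec
    if not spec.is_baseline:
        try:
            return factor_pattern_probs(
                fit.loadings_hat, fit.phi_hat, fit.thresholds_hat, spec.m,
                n_nodes=n_nodes,
            )
        except ValueError:
            pass  # Heywood case: fall back to the rectangle integrator
    rho = np.asarray(fit.implied_rho_hat, float)
    w, v = np.linalg.eigh(rho)
    if w.min() < 1e-8:
        # repair an indefinite implied matrix (possible for Heywood fits)
        w = np.maximum(w, 1e-8)
        rho = v @ np.diag(w) @ v.T
        s = np.sqrt(np.diag(rho))
        rho = rho / np.outer(s, s)
    return all_pattern_probs(rho, fit.thresholds_hat, spec.m, spec.k, tol=tol)


def compute_cf(pattern_counts: Mapping[tuple[int, ...], int],
               fitted_probs: PatternProbabilities,
               N: int, n_params: int, m: int, k: int,
               alpha: float = 0.05) -> tuple[FitStatistic, FitStatistic]:
    """C_F = 2N sum_r p_r ln(p_r / pi_hat_r) over observed patterns.

    Returns the statistic twice: once with df = m^k - n - 1 and once with
    the observed-pattern df = u_r - n - 1 (clamped at 1 with a flag when
    nonpositive).  Unobserved patterns contribute zero.
    """
    flags: list[str] = []
    total = 0.0
    floored = 0
    for pattern, count in pattern_counts.items():
        if count == 0:
            continue
        p_r = count / N
        pi_r = fitted_probs.prob(pattern)
        if pi_r < _CF_FLOOR:
            pi_r = _CF_FLOOR
            floored += 1
        total += p_r * np.log(p_r / pi_r)
    value = 2.0 * N * total
    if floored:
        flags.append(f"{floored} observed patterns at the probability floor")

    df_f = m**k - n_params - 1
    u_r = sum(1 for c in pattern_counts.values() if c > 0)
    df_star = u_r - n_params - 1
    star_flags = list(flags)
    if df_star < 1:
        star_flags.append(f"df* = {df_star} clamped to 1")
        df_star = 1

    p_f = chisq_pvalue(value, df_f)
    p_star = chisq_pvalue(value, df_star)
    return (
        FitStatistic("CF", value, df_f, p_f, alpha, p_f < alpha, tuple(flags)),
        FitStatistic("CF_star", value, df_star, p_star, alpha,
                     p_star < alpha, tuple(star_flags)),
    )


def compute_cm(cf_model: FitStatistic, cf_baseline: FitStatistic,
               spec1: FactorModelSpec, alpha: float = 0.05) -> FitStatistic:
    """C_M = C_F(model of interest) - C_F(baseline).

    df_M = k(k-1)/2 + k(m-1) - n1 with n1 counting *all* parameters of the
    model of interest, thresholds included.  A negative value (possible in
    finite samples because PML estimates do not maximize the full-pattern
    likelihood) is reported as-is with p = 1 and a flag, never truncated.
    """
    k, m = spec1.k, spec1.m
    value = cf_model.value - cf_baseline.value
    df = k * (k - 1) // 2 + k * (m - 1) - spec1.n_params
    flags: list[str] = []
    if value < 0:
        flags.append("negative C_M (finite-sample artifact)")
    p = chisq_pvalue(value, df)
    return FitStatistic("CM", value, df, p, alpha, p < alpha, tuple(flags))


def compute_cp(pairwise_tables: Mapping[tuple[int, int], np.ndarray],
               fit: PMLFit, alpha: float = 0.05) -> CPResult:
    """Per-pair C_P_ij = 2N sum p ln(p / pi_hat) and the max-rule decision.

    pi_hat are the model-implied bivariate cell probabilities at the PML
    estimates.  df_P = m^2 - 2m; for dichotomous items df_P = 0, so the
    underlying-bivariate-normality hypothesis cannot be tested and a
    ValueError is raised.
    """
    spec = fit.spec
    m, k = spec.m, spec.k
    if m < 3:
        raise ValueError(
            "C_P is undefined for m = 2: df_P = m^2 - 2m = 0, the underlying "
            "bivariate normal distribution cannot be tested"
        )
    df = m * m - 2 * m
    alpha_star = bonferroni_alpha(alpha, k)
    tau = fit.thresholds_hat.tau
    rho = fit.implied_rho_hat
    stats: dict[tuple[int, int], float] = {}
    for (i, j), table in pairwise_tables.items():
        table = np.asarray(table, float)
        N = table.sum()
        p = table / N
        pi = np.maximum(cell_prob_table(rho[i, j], tau[i], tau[j]), _CF_FLOOR)
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(p > 0, p * np.log(p / pi), 0.0)
        stats[(i, j)] = float(2.0 * N * terms.sum())
    # first pair in (i < j) lexicographic order wins ties; the decision
    # depends only on the max value
    max_pair = max(sorted(stats), key=lambda ij: stats[ij])
    value = stats[max_pair]
    p_max = chisq_pvalue(value, df)
    overall = FitStatistic("CP", value, df, p_max, alpha_star,
                           p_max < alpha_star)
    return CPResult(pair_stats=stats, df=df, alpha=alpha,
                    alpha_star=alpha_star, max_pair=max_pair,
                    statistic=overall)
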