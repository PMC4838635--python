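"""Monte Carlo harness: calibration and power of the PML fit statistics.

The design crosses sample size (200, 500, 1000) with the number of response
categories (2, 3, 4).  For every replication a dataset is drawn from the
two-factor population model, the baseline / one-factor / two-factor models
are fitted by PML, and the requested statistics are evaluated at the 5%
level.  Rejection rates over replications estimate the type-I error for
correctly specified models (baseline, two-factor) and power for the
misspecified one-factor model.

Replication r of a condition uses generator seed ``base_seed + r``; since
the latent draw depends only on the seed and the sample size, the same
continuous scores underlie the 2-, 3- and 4-category versions of a
replication, exactly as in a design that discretizes one set of continuous
scores three ways.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np
import pandas as pd

from .data import (
    POPULATION_LOADINGS,
    POPULATION_PHI,
    GenerationConfig,
    generate,
)
from .gof import compute_cf, compute_cm, compute_cp, fitted_pattern_probs
from .models import study_model
from .pml import FitOptions, fit_pml

__all__ = ["StudyDesign", "ConditionResult", "run_condition",
           "rejection_ci", "accuracy_summary", "run_study"]

logger = logging.getLogger(__name__)

_MODELS = ("baseline", "one_factor", "two_factor")


@dataclass(frozen=True)
class StudyDesign:
    """What to simulate and how often."""

    sample_sizes: tuple[int, ...] = (200, 500, 1000)
    category_counts: tuple[int, ...] = (2, 3, 4)
    replications: int = 1000
    base_seed: int = 0
    alpha: float = 0.05
    models: tuple[str, ...] = _MODELS
    statistics: tuple[str, ...] = ("CF", "CM", "CP")
    cf_tol: float = 1e-5        # QMC tolerance for baseline pattern tables

    def __post_init__(self):
        if self.replications < 1:
            raise ValueError("need at least one replication")
        unknown = set(self.statistics) - {"CF", "CM", "CP"}
        if unknown:
            raise ValueError(f"unknown statistics: {sorted(unknown)}")
        if "CM" in self.statistics and "baseline" not in self.models:
            raise ValueError("C_M needs the baseline model in the design")


@dataclass
class ConditionResult:
    """Aggregated results of one (N, m) condition."""

    N: int
    m: int
    replications: int
    table: pd.DataFrame               # per (model, statistic) summary
    estimates: dict[str, np.ndarray]  # structural estimates per model
    n_nonconverged: int
    n_excluded: int                   # replications with no computable stats

    def __repr__(self):
        return (f"ConditionResult(N={self.N}, m={self.m}, "
                f"R={self.replications}, rows={len(self.table)})")


def rejection_ci(rate: float, R: int) -> tuple[float, float]:
    """95% Wald interval rate +- 1.96 sqrt(rate(1-rate)/R), clipped to [0,1]."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    half = 1.96 * np.sqrt(rate * (1.0 - rate) / R)
    return (max(0.0, rate - half), min(1.0, rate + half))


def _structural_estimates(fit) -> np.ndarray:
    spec = fit.spec
    if spec.is_baseline:
        return fit.rho_hat[np.triu_indices(spec.k, 1)]
    parts = [fit.loadings_hat[spec.loading_mask]]
    iu = np.triu_indices(spec.q, 1)
    free = spec.phi_free[iu]
    if free.any():
        parts.append(fit.phi_hat[iu][free])
    return np.concatenate(parts)


def run_condition(design: StudyDesign, N: int, m: int) -> ConditionResult:
    """Run all replications of one (N, m) cell and aggregate.

    Non-converged fits are flagged and counted; their statistics are still
    recorded when computable (the reported denominator says what was used).
    """
    alpha = design.alpha
    specs = {mid: study_model(mid, k=6, m=m) for mid in design.models}
    want_cf = "CF" in design.statistics
    want_cm = "CM" in design.statistics
    want_cp = "CP" in design.statistics and m >= 3

    records: list[dict] = []
    estimates: dict[str, list[np.ndarray]] = {mid: [] for mid in design.models}
    n_nonconv = 0
    n_excluded = 0
    options = FitOptions()

    for r in range(design.replications):
        seed = design.base_seed + r
        ds = generate(GenerationConfig(n=N, m=m, seed=seed))
        fits = {}
        try:
            for mid in design.models:
                fits[mid] = fit_pml(ds, specs[mid], options)
        except Exception:
            logger.exception("replication %d (N=%d, m=%d) failed", r, N, m)
            n_excluded += 1
            continue
        rep_nonconv = any(not f.converged for f in fits.values())
        if rep_nonconv:
            n_nonconv += 1
        for mid, fit in fits.items():
            estimates[mid].append(_structural_estimates(fit))

        cf_stats = {}
        if want_cf or want_cm:
            for mid in design.models:
                probs = fitted_pattern_probs(fits[mid], tol=design.cf_tol)
                cf_stats[mid] = compute_cf(
                    ds.pattern_counts, probs, N,
                    specs[mid].n_params, m, 6, alpha=alpha,
                )
        for mid in design.models:
            row = {"rep": r, "model": mid, "converged": fits[mid].converged}
            if mid in cf_stats:
                cf, cf_star = cf_stats[mid]
                if want_cf:
                    records.append(row | {
                        "statistic": "CF", "value": cf.value, "df": cf.df,
                        "reject": cf.reject,
                    })
                    records.append(row | {
                        "statistic": "CF_star", "value": cf_star.value,
                        "df": cf_star.df, "reject": cf_star.reject,
                    })
            if want_cm and mid != "baseline":
                cm = compute_cm(cf_stats[mid][0], cf_stats["baseline"][0],
                                specs[mid], alpha=alpha)
                records.append(row | {
                    "statistic": "CM", "value": cm.value, "df": cm.df,
                    "reject": cm.reject,
                })
            if want_cp:
                cp = compute_cp(ds.pairwise_tables, fits[mid], alpha=alpha)
                records.append(row | {
                    "statistic": "CP", "value": cp.statistic.value,
                    "df": cp.df, "reject": cp.statistic.reject,
                })
        if (r + 1) % 100 == 0:
            logger.info("condition N=%d m=%d: %d/%d replications",
                        N, m, r + 1, design.replications)

    raw = pd.DataFrame.from_records(records)
    rows = []
    if not raw.empty:
        for (mid, stat), grp in raw.groupby(["model", "statistic"], sort=False):
            R_used = len(grp)
            rr = float(grp["reject"].mean())
            lo, hi = rejection_ci(rr, R_used)
            rows.append({
                "model": mid, "statistic": stat,
                "mean": float(grp["value"].mean()),
                "sd": float(grp["value"].std(ddof=1)) if R_used > 1 else 0.0,
                "df_mean": float(grp["df"].mean()),
                "df_sd": float(grp["df"].std(ddof=1)) if R_used > 1 else 0.0,
                "rejection_rate": rr, "ci_low": lo, "ci_high": hi,
                "n_used": R_used,
            })
    table = pd.DataFrame(rows)
    return ConditionResult(
        N=N, m=m, replications=design.replications, table=table,
        estimates={mid: np.asarray(v) for mid, v in estimates.items()},
        n_nonconverged=n_nonconv, n_excluded=n_excluded,
    )


def accuracy_summary(estimates: np.ndarray, truth: np.ndarray,
                     names: list[str] | None = None) -> pd.DataFrame:
    """Accuracy and efficiency of estimates over replications.

    ``abs_bias`` is the absolute difference between the replication-averaged
    estimate and the population value (the accuracy measure); ``sd`` is the
    standard deviation of the estimates (the efficiency measure);
    ``mean_abs_dev`` the per-replication mean absolute deviation.  A
    grand-average row is appended.  ``estimates`` is (replications, params).
    """
    estimates = np.asarray(estimates, float)
    if estimates.size == 0:
        raise ValueError("no estimates to summarize")
    truth = np.asarray(truth, float)
    abs_bias = np.abs(estimates.mean(axis=0) - truth)
    mad = np.abs(estimates - truth).mean(axis=0)
    sd = estimates.std(axis=0, ddof=1)
    if names is None:
        names = [f"param{i + 1}" for i in range(truth.size)]
    df = pd.DataFrame({"parameter": names, "abs_bias": abs_bias,
                       "mean_abs_dev": mad, "sd": sd})
    grand = pd.DataFrame({
        "parameter": ["(average)"],
        "abs_bias": [abs_bias.mean()],
        "mean_abs_dev": [mad.mean()],
        "sd": [sd.mean()],
    })
    return pd.concat([df, grand], ignore_index=True)


def two_factor_truth() -> np.ndarray:
    """Population structural parameters in estimate order (7 loadings, phi)."""
    spec = study_model("two_factor", 6, 2)
    return np.concatenate([
        POPULATION_LOADINGS[spec.loading_mask], [POPULATION_PHI[0, 1]]
    ])


def run_study(design: StudyDesign) -> dict[tuple[int, int], ConditionResult]:
    """All (N, m) conditions of the design."""
    out = {}
    for N in design.sample_sizes:
        for m in design.category_counts:
            logger.info("running condition N=%d m=%d", N, m)
            out[(N, m)] = run_condition(design, N, m)
    return out
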