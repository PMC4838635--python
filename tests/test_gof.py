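"""The C_F, C_M and C_P statistics and their decision rules."""

import numpy as np
import pytest

from pmlfa import (
    FactorModelSpec,
    FitStatistic,
    GenerationConfig,
    PMLFit,
    ThresholdSet,
    bonferroni_alpha,
    cell_prob_table,
    chisq_pvalue,
    compute_cf,
    compute_cm,
    compute_cp,
    fit_pml,
    fitted_pattern_probs,
    generate,
    study_model,
)
from pmlfa.patterns import PatternProbabilities


class TestChisqPvalue:
    def test_zero_statistic(self):
        assert chisq_pvalue(0.0, 5) == 1.0

    def test_monotone_in_value(self):
        ps = [chisq_pvalue(v, 7) for v in (1.0, 5.0, 7.0, 12.0, 30.0)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_reference_value(self):
        # upper tail of chi-square(7) at 7.738
        assert chisq_pvalue(7.738, 7) == pytest.approx(0.356, abs=5e-4)

    def test_negative_value_maps_to_one(self):
        assert chisq_pvalue(-3.0, 4) == 1.0

    def test_invalid_df(self):
        with pytest.raises(ValueError):
            chisq_pvalue(1.0, 0)


def _uniform_table(m, k):
    n = m**k
    return PatternProbabilities(probs=np.full(n, 1.0 / n), m=m, k=k,
                                total_raw=1.0, renormalized=False)


class TestComputeCF:
    def test_zero_when_observed_equals_fitted(self):
        m, k, N = 2, 3, 80
        tab = _uniform_table(m, k)
        counts = {pat: N // 8 for pat in
                  [tuple(1 + ((i >> s) & 1) for s in range(k)) for i in range(8)]}
        cf, cf_star = compute_cf(counts, tab, N, n_params=3, m=m, k=k)
        assert cf.value == pytest.approx(0.0, abs=1e-12)
        assert cf.df == 2**3 - 3 - 1
        assert cf_star.df == 8 - 3 - 1
        assert not cf.reject

    def test_df_star_clamped_with_flag(self):
        tab = _uniform_table(2, 3)
        counts = {(1, 1, 1): 5, (2, 2, 2): 5}
        cf, cf_star = compute_cf(counts, tab, 10, n_params=3, m=2, k=3)
        assert cf_star.df == 1
        assert any("clamped" in f for f in cf_star.flags)

    def test_unobserved_patterns_contribute_nothing(self):
        tab = _uniform_table(2, 3)
        counts = {(1, 1, 1): 10, (2, 2, 2): 0}
        cf, _ = compute_cf(counts, tab, 10, n_params=3, m=2, k=3)
        assert cf.value == pytest.approx(2 * 10 * np.log(1 / 0.125), abs=1e-9)


class TestComputeCM:
    def test_identical_models_give_zero(self):
        spec = study_model("one_factor", 6, 2)
        cf = FitStatistic("CF", 50.0, 51, 0.5, 0.05, False)
        cm = compute_cm(cf, cf, spec)
        assert cm.value == 0.0
        assert not cm.reject

    @pytest.mark.parametrize("m", [2, 3, 4])
    def test_df_for_study_models(self, m):
        cf1 = FitStatistic("CF", 60.0, 1, 0.5, 0.05, False)
        cf0 = FitStatistic("CF", 50.0, 1, 0.5, 0.05, False)
        assert compute_cm(cf1, cf0, study_model("one_factor", 6, m)).df == 9
        assert compute_cm(cf1, cf0, study_model("two_factor", 6, m)).df == 7

    def test_negative_value_flagged_never_truncated(self):
        spec = study_model("two_factor", 6, 2)
        cf1 = FitStatistic("CF", 40.0, 49, 0.5, 0.05, False)
        cf0 = FitStatistic("CF", 45.0, 42, 0.5, 0.05, False)
        cm = compute_cm(cf1, cf0, spec)
        assert cm.value == -5.0
        assert cm.p_value == 1.0
        assert any("negative" in f for f in cm.flags)
        assert not cm.reject

    def test_additivity_with_computed_cf(self, pop_dataset_m2):
        ds = pop_dataset_m2
        s0 = study_model("baseline", 6, 2)
        s1 = study_model("one_factor", 6, 2)
        f0, f1 = fit_pml(ds, s0), fit_pml(ds, s1)
        cf0 = compute_cf(ds.pattern_counts, fitted_pattern_probs(f0, tol=1e-5),
                         ds.n, s0.n_params, 2, 6)[0]
        cf1 = compute_cf(ds.pattern_counts, fitted_pattern_probs(f1),
                         ds.n, s1.n_params, 2, 6)[0]
        cm = compute_cm(cf1, cf0, s1)
        assert cf0.value + cm.value == pytest.approx(cf1.value, abs=1e-10)


def _synthetic_baseline_fit(k, m, rho, tau):
    spec = FactorModelSpec(k=k, m=m, model_id="baseline")
    return PMLFit(spec=spec, thresholds_hat=tau, loadings_hat=None,
                  phi_hat=None, rho_hat=rho, implied_rho_hat=rho,
                  objective=0.0, converged=True, iterations=0,
                  grad_norm=0.0, N=0)


class TestComputeCP:
    def test_m2_cannot_be_tested(self, pop_dataset_m2):
        fit = fit_pml(pop_dataset_m2, study_model("baseline", 6, 2))
        with pytest.raises(ValueError, match="cannot be tested"):
            compute_cp(pop_dataset_m2.pairwise_tables, fit)

    @pytest.mark.parametrize("m,df", [(3, 3), (4, 8)])
    def test_pair_degrees_of_freedom(self, m, df):
        ds = generate(GenerationConfig(n=150, m=m, seed=1))
        fit = fit_pml(ds, study_model("baseline", 6, m))
        cp = compute_cp(ds.pairwise_tables, fit)
        assert cp.df == df
        assert len(cp.pair_stats) == 15

    def test_bonferroni_level(self):
        assert bonferroni_alpha(0.05, 6) == pytest.approx(0.05 / 15)

    def test_perfect_fit_gives_zero_everywhere(self):
        # tables constructed to match the model-implied probabilities exactly
        k, m, N = 3, 3, 900
        rho = np.array([[1.0, 0.4, 0.2], [0.4, 1.0, 0.3], [0.2, 0.3, 1.0]])
        tau = ThresholdSet(np.tile([-0.5, 0.7], (3, 1)))
        fit = _synthetic_baseline_fit(k, m, rho, tau)
        tables = {
            (i, j): N * cell_prob_table(rho[i, j], tau.tau[i], tau.tau[j])
            for i in range(k - 1) for j in range(i + 1, k)
        }
        cp = compute_cp(tables, fit)
        assert cp.statistic.value == pytest.approx(0.0, abs=1e-9)
        assert not cp.statistic.reject

    def test_overall_is_max_and_ties_break_lexicographically(self):
        ds = generate(GenerationConfig(n=300, m=3, seed=5))
        fit = fit_pml(ds, study_model("baseline", 6, 3))
        cp = compute_cp(ds.pairwise_tables, fit)
        assert cp.statistic.value == max(cp.pair_stats.values())
        argmax = [ij for ij, v in cp.pair_stats.items()
                  if v == cp.statistic.value]
        assert cp.max_pair == min(argmax)
        assert cp.statistic.reject == (
            chisq_pvalue(cp.statistic.value, cp.df) < cp.alpha_star
        )
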