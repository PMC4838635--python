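"""The pairwise-likelihood objective, its gradient, and the PML fitter."""

import numpy as np
import pytest
from scipy.integrate import dblquad
from scipy.optimize import minimize
from scipy.special import ndtr
from scipy.stats import multivariate_normal

from pmlfa import (
    FactorModelSpec,
    GenerationConfig,
    OrdinalDataset,
    ParameterVector,
    ThresholdSet,
    bivariate_cell_prob,
    cell_prob_table,
    fit_pml,
    generate,
    pairwise_loglik,
    study_model,
)
from pmlfa.pml import _PairwiseObjective


class TestBivariateCellProb:
    def test_independence_with_median_split(self):
        for a in (1, 2):
            for b in (1, 2):
                assert bivariate_cell_prob(0.0, [0.0], [0.0], a, b) == \
                    pytest.approx(0.25, abs=1e-14)

    def test_independence_factorizes(self):
        ti, tj = [-0.3, 0.9], [-1.1, 0.2]
        table = cell_prob_table(0.0, ti, tj)
        pi = np.diff(np.concatenate([[0.0], ndtr(ti), [1.0]]))
        pj = np.diff(np.concatenate([[0.0], ndtr(tj), [1.0]]))
        assert np.allclose(table, np.outer(pi, pj), atol=1e-14)

    def test_cells_sum_to_one(self):
        table = cell_prob_table(0.72, [-0.6, 0.6], [-0.6, 0.6])
        assert table.sum() == pytest.approx(1.0, abs=1e-12)

    def test_against_adaptive_quadrature(self):
        rho = 0.72
        dens = multivariate_normal(mean=[0, 0], cov=[[1, rho], [rho, 1]]).pdf
        ref, err = dblquad(lambda y, x: dens([x, y]), -8.5, -0.6,
                           -8.5, -0.6, epsabs=1e-12)
        got = bivariate_cell_prob(rho, [-0.6, 0.6], [-0.6, 0.6], 1, 1)
        assert got == pytest.approx(ref, abs=1e-8)

    def test_invalid_rho(self):
        with pytest.raises(ValueError, match="rho"):
            bivariate_cell_prob(1.0, [0.0], [0.0], 1, 1)


class TestPairwiseLoglik:
    def test_hand_computed_toy_table(self):
        codes = np.concatenate([
            np.tile([1, 1], (30, 1)), np.tile([1, 2], (20, 1)),
            np.tile([2, 1], (10, 1)), np.tile([2, 2], (40, 1)),
        ])
        ds = OrdinalDataset(codes=codes, m=2)
        spec = FactorModelSpec(k=2, m=2, model_id="baseline")
        pv = ParameterVector.pack(spec, ThresholdSet(np.zeros((2, 1))),
                                  rho=np.array([0.0]))
        # all four cells have probability 1/4
        assert pairwise_loglik(ds, pv, spec) == pytest.approx(
            100 * np.log(0.25), abs=1e-9
        )

    def test_gibbs_inequality_at_matching_proportions(self):
        codes = np.concatenate([
            np.tile([1, 1], (100, 1)), np.tile([1, 2], (100, 1)),
            np.tile([2, 1], (100, 1)), np.tile([2, 2], (100, 1)),
        ])
        ds = OrdinalDataset(codes=codes, m=2)
        spec = FactorModelSpec(k=2, m=2, model_id="baseline")
        tau0 = ThresholdSet(np.zeros((2, 1)))
        best = pairwise_loglik(ds, ParameterVector.pack(spec, tau0,
                                                        rho=np.array([0.0])), spec)
        assert best == pytest.approx(400 * np.log(0.25))
        rng = np.random.default_rng(3)
        for _ in range(10):
            tau = ThresholdSet(rng.normal(0, 0.5, (2, 1)))
            r = rng.uniform(-0.8, 0.8, 1)
            other = pairwise_loglik(ds, ParameterVector.pack(spec, tau, rho=r), spec)
            assert other <= best + 1e-9


@pytest.mark.parametrize("m,model_id", [
    (2, "baseline"), (2, "two_factor"),
    (3, "one_factor"), (3, "baseline"),
    (4, "two_factor"), (4, "one_factor"),
])
def test_analytic_gradient_matches_finite_differences(m, model_id, rng):
    spec = study_model(model_id, 6, m)
    ds = generate(GenerationConfig(n=300, m=m, seed=21))
    obj = _PairwiseObjective(ds, spec)
    ut = np.column_stack(
        [rng.uniform(-1, -0.5, 6)] + [rng.uniform(-1, 0, 6)] * (m - 2)
    )
    us = rng.uniform(-0.5, 0.8, spec.n_structural)
    u = np.concatenate([ut.ravel(), us])
    f, g = obj.value_and_grad(u)
    h = 1e-6
    for i in range(u.size):
        up, um = u.copy(), u.copy()
        up[i] += h
        um[i] -= h
        num = (obj.value_and_grad(up)[0] - obj.value_and_grad(um)[0]) / (2 * h)
        assert g[i] == pytest.approx(num, rel=1e-4, abs=1e-8)


class TestFitPML:
    def test_k2_matches_independent_polychoric_ml(self):
        # classical one-step polychoric ML on a single pair, maximized with
        # an independent parameterization and scipy's own bivariate CDF
        corr = np.array([[1.0, 0.72], [0.72, 1.0]])
        tau = ThresholdSet(np.array([[-0.6, 0.6], [-0.6, 0.6]]))
        ds = generate(GenerationConfig(n=400, m=3, seed=77, corr=corr,
                                       thresholds=tau))
        spec = FactorModelSpec(k=2, m=3, model_id="baseline")
        fit = fit_pml(ds, spec)
        assert fit.converged

        table = ds.pairwise_tables[(0, 1)].astype(float)

        def cellp(r, ti, tj):
            mv = multivariate_normal(mean=[0, 0], cov=[[1, r], [r, 1]])
            grid = np.zeros((4, 4))
            pts = [np.concatenate([[-30.0], ti, [30.0]]),
                   np.concatenate([[-30.0], tj, [30.0]])]
            for a in range(4):
                for b in range(4):
                    grid[a, b] = mv.cdf([pts[0][a], pts[1][b]])
            return np.diff(np.diff(grid, axis=0), axis=1)

        def nll(theta):
            t1, g1, t2, g2, z = theta
            ti = np.array([t1, t1 + np.exp(g1)])
            tj = np.array([t2, t2 + np.exp(g2)])
            pi = np.maximum(cellp(np.tanh(z), ti, tj), 1e-300)
            return -np.sum(table * np.log(pi))

        x0 = np.array([-0.6, np.log(1.2), -0.6, np.log(1.2), np.arctanh(0.7)])
        res = minimize(nll, x0, method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000})
        rho_oracle = np.tanh(res.x[4])
        assert fit.rho_hat[0, 1] == pytest.approx(rho_oracle, abs=1e-4)
        tau_oracle = np.array([res.x[0], res.x[0] + np.exp(res.x[1])])
        assert np.allclose(fit.thresholds_hat.tau[0], tau_oracle, atol=1e-4)

    def test_nested_objective_ordering(self, pop_dataset_m3, study_specs_m3):
        fits = {mid: fit_pml(pop_dataset_m3, spec)
                for mid, spec in study_specs_m3.items()}
        assert fits["baseline"].objective >= fits["two_factor"].objective - 1e-6
        assert fits["two_factor"].objective >= fits["one_factor"].objective - 1e-6

    def test_monotone_relabeling_leaves_fit_unchanged(self, pop_dataset_m3):
        ds = pop_dataset_m3
        relabelled = np.array([2, 5, 9])[ds.codes - 1]   # increasing map
        ranks = np.searchsorted(np.unique(relabelled), relabelled) + 1
        ds2 = OrdinalDataset(codes=ranks, m=3)
        spec = study_model("two_factor", 6, 3)
        f1, f2 = fit_pml(ds, spec), fit_pml(ds2, spec)
        assert np.array_equal(ds.codes, ds2.codes)
        assert np.allclose(f1.implied_rho_hat, f2.implied_rho_hat)

    def test_reverse_coding_mirrors_thresholds(self, pop_dataset_m3):
        ds = pop_dataset_m3
        rev = OrdinalDataset(codes=ds.m + 1 - ds.codes, m=ds.m)
        spec = study_model("baseline", 6, 3)
        f, fr = fit_pml(ds, spec), fit_pml(rev, spec)
        assert np.allclose(fr.rho_hat, f.rho_hat, atol=5e-5)
        assert np.allclose(fr.thresholds_hat.tau,
                           -f.thresholds_hat.tau[:, ::-1], atol=5e-5)

    def test_empty_category_capped_and_flagged(self):
        rng = np.random.default_rng(0)
        codes = rng.integers(1, 5, size=(60, 3))
        codes[:, 0] = np.maximum(codes[:, 0], 2)   # category 1 never observed
        ds = OrdinalDataset(codes=codes, m=4)
        spec = FactorModelSpec(k=3, m=4, model_id="baseline")
        fit = fit_pml(ds, spec)
        assert any("empty observed category" in w for w in fit.warnings_)
        assert fit.thresholds_hat.tau[0, 0] <= -4.0

    def test_consistency_against_generating_correlations(self):
        from pmlfa import population_correlations

        ds = generate(GenerationConfig(n=50_000, m=3, seed=123))
        fit = fit_pml(ds, study_model("baseline", 6, 3))
        assert np.max(np.abs(fit.implied_rho_hat - population_correlations())) < 0.025

    def test_two_factor_loadings_unbiased(self):
        # parameter recovery at N=1000 over 200 replications
        from pmlfa import POPULATION_LOADINGS, POPULATION_PHI

        spec = study_model("two_factor", 6, 3)
        est = []
        for r in range(200):
            ds = generate(GenerationConfig(n=1000, m=3, seed=3000 + r))
            f = fit_pml(ds, spec)
            est.append(np.concatenate([
                f.loadings_hat[spec.loading_mask], [f.phi_hat[0, 1]]
            ]))
        est = np.array(est)
        truth = np.concatenate([
            POPULATION_LOADINGS[spec.loading_mask], [POPULATION_PHI[0, 1]]
        ])
        se = est.std(axis=0, ddof=1) / np.sqrt(len(est))
        assert np.all(np.abs(est.mean(axis=0) - truth) < 3 * se)
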