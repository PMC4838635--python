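"""Pairwise maximum likelihood (PML) estimation for ordinal factor models.

The estimator maximizes, in a single step over thresholds and structural
parameters jointly, the composite log-likelihood

    l = N * sum_{i<j} sum_{a,b} p_ab^{(ij)} * ln pi_ab^{(ij)}(rho_ij, tau_i, tau_j),

where p are observed bivariate proportions and pi are standard-bivariate-
normal rectangle probabilities between consecutive thresholds.  The
multinomial constant is dropped throughout, identically for every model, so
likelihood differences are unaffected.

Optimization is quasi-Newton (L-BFGS-B) on transformed parameters: each
item's thresholds are coded as first threshold plus log-gaps (ordering is
automatic), correlation-type parameters through atanh, loadings untouched.
Gradients are analytic: rectangle-probability derivatives with respect to
the correlation come from Plackett's identity and with respect to a
threshold from the phi * conditional-Phi form, then chained through the
factor structure and the transforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
from scipy.optimize import minimize
from scipy.special import ndtr, ndtri

from .bvn import bvn_cdf, bvn_cdf_dx, bvn_pdf
from .data import OrdinalDataset
from .models import FactorModelSpec, ParameterVector, ThresholdSet

__all__ = [
    "PMLFit",
    "FitOptions",
    "bivariate_cell_prob",
    "cell_prob_table",
    "pairwise_loglik",
    "polychoric_twostep",
    "fit_pml",
]

PROB_FLOOR = 1e-12

# bounds on the transformed scale: |tau| effectively capped near 6,
# log-gaps kept positive-definite, atanh(correlation) kept finite
_TAU_BOUND = 6.0
_GAP_LOG_LO, _GAP_LOG_HI = -10.0, 2.6
_ATANH_BOUND = 5.0  # |rho| <= tanh(5) ~ 0.9999
_LOADING_BOUND = 3.0


def _soft_clip_corr(rho: np.ndarray, edge: float = 0.999):
    """Identity on [-edge, edge]; smooth squash asymptoting inside (-1, 1).

    Keeps implied pair correlations from factor structures valid during
    line searches without ever distorting values in the realistic range.
    Returns (squashed value, derivative).
    """
    w = (1.0 - edge) * 0.999
    out = np.asarray(rho, float).copy()
    deriv = np.ones_like(out)
    hi = out > edge
    lo = out < -edge
    if np.any(hi):
        t = np.tanh((out[hi] - edge) / w)
        out[hi] = edge + w * t
        deriv[hi] = 1.0 - t * t
    if np.any(lo):
        t = np.tanh((out[lo] + edge) / w)
        out[lo] = -edge + w * t
        deriv[lo] = 1.0 - t * t
    return out, deriv


def cell_prob_table(rho: float, tau_i: np.ndarray, tau_j: np.ndarray) -> np.ndarray:
    """All m_i x m_j bivariate cell probabilities for one item pair."""
    tau_i = np.atleast_1d(np.asarray(tau_i, float))
    tau_j = np.atleast_1d(np.asarray(tau_j, float))
    ti = np.concatenate([[-np.inf], tau_i, [np.inf]])
    tj = np.concatenate([[-np.inf], tau_j, [np.inf]])
    grid = bvn_cdf(ti[:, None], tj[None, :], rho)
    cells = np.diff(np.diff(grid, axis=0), axis=1)
    return np.clip(cells, 0.0, 1.0)


def bivariate_cell_prob(rho, tau_i, tau_j, x_i: int, x_j: int) -> float:
    """P(X_i = x_i, X_j = x_j) under the underlying bivariate normal.

    Categories are 1-based codes; |rho| must be below 1.
    """
    if not abs(rho) < 1.0:
        raise ValueError("|rho| must be < 1")
    table = cell_prob_table(rho, tau_i, tau_j)
    return float(table[x_i - 1, x_j - 1])


# ---------------------------------------------------------------------------
# objective machinery
# ---------------------------------------------------------------------------


class _PairwiseObjective:
    """Negative mean pairwise log-likelihood and its analytic gradient.

    Operates on the transformed parameter vector; caches the observed
    bivariate proportion tables of one dataset.
    """

    def __init__(self, dataset: OrdinalDataset, spec: FactorModelSpec,
                 floor: float = PROB_FLOOR):
        if dataset.m != spec.m:
            raise ValueError("dataset category count does not match the spec")
        if dataset.k != spec.k:
            raise ValueError("dataset item count does not match the spec")
        self.spec = spec
        self.k, self.m = spec.k, spec.m
        self.N = dataset.n
        self.floor = floor
        pairs = spec.pair_indices()
        self.I = np.array([i for i, _ in pairs])
        self.J = np.array([j for _, j in pairs])
        self.P = len(pairs)
        tables = dataset.pairwise_tables
        self.obs = np.stack([tables[p] for p in pairs]).astype(float) / self.N
        self.floored_cells = 0

    # -- transform <-> natural ------------------------------------------

    def n_free(self) -> int:
        return self.spec.n_params

    def split(self, u: np.ndarray):
        nt = self.spec.n_thresholds
        return u[:nt].reshape(self.k, self.m - 1), u[nt:]

    def decode_thresholds(self, ut: np.ndarray) -> np.ndarray:
        tau = np.empty_like(ut)
        tau[:, 0] = ut[:, 0]
        if self.m > 2:
            tau[:, 1:] = ut[:, 0:1] + np.cumsum(np.exp(ut[:, 1:]), axis=1)
        return tau

    def encode_thresholds(self, tau: np.ndarray) -> np.ndarray:
        ut = np.empty_like(tau)
        ut[:, 0] = tau[:, 0]
        if self.m > 2:
            gaps = np.maximum(np.diff(tau, axis=1), 1e-8)
            ut[:, 1:] = np.log(gaps)
        return ut

    def decode_structural(self, us: np.ndarray):
        spec = self.spec
        if spec.is_baseline:
            return np.tanh(us)
        nl = int(spec.loading_mask.sum())
        lam = np.zeros((spec.k, spec.q))
        lam[spec.loading_mask] = us[:nl]
        phi = np.eye(spec.q)
        iu = np.triu_indices(spec.q, 1)
        free = spec.phi_free[iu]
        vals = np.zeros(free.size)
        vals[free] = np.tanh(us[nl:])
        phi[iu] = vals
        phi = phi + phi.T - np.diag(np.diag(phi))
        return lam, phi

    def rho_vector(self, us: np.ndarray):
        """-> (rho per pair, cached structural pieces for the chain rule)."""
        spec = self.spec
        if spec.is_baseline:
            rho = np.tanh(us)
            return rho, None
        lam, phi = self.decode_structural(us)
        R = lam @ phi @ lam.T
        return R[self.I, self.J], (lam, phi, R)

    # -- value and gradient ----------------------------------------------

    def value_and_grad(self, u: np.ndarray):
        spec, m = self.spec, self.m
        ut, us = self.split(u)
        tau = self.decode_thresholds(ut)          # (k, m-1)
        rho_raw, struct = self.rho_vector(us)     # (P,)
        rho, drho_soft = _soft_clip_corr(rho_raw)
        Ti, Tj = tau[self.I], tau[self.J]         # (P, m-1)
        rb = rho[:, None, None]

        # padded CDF grid -> cell probabilities
        G = np.zeros((self.P, m + 1, m + 1))
        if m > 1:
            G[:, 1:m, 1:m] = bvn_cdf(Ti[:, :, None], Tj[:, None, :], rb)
        G[:, m, 1:m] = ndtr(Tj)
        G[:, 1:m, m] = ndtr(Ti)
        G[:, m, m] = 1.0
        cells = np.diff(np.diff(G, axis=1), axis=2)   # (P, m, m)

        clipped = cells < self.floor
        self.floored_cells = int(np.count_nonzero(clipped & (self.obs > 0)))
        safe = np.maximum(cells, self.floor)
        f = -np.sum(self.obs * np.log(safe))

        # dl/dpi, zero where nothing observed
        W = np.where(self.obs > 0, self.obs / safe, 0.0)

        # d pi / d rho via Plackett: double difference of the density grid
        D = np.zeros((self.P, m + 1, m + 1))
        D[:, 1:m, 1:m] = bvn_pdf(Ti[:, :, None], Tj[:, None, :], rb)
        dpi_drho = np.diff(np.diff(D, axis=1), axis=2)
        g_rho = -np.einsum("pab,pab->p", W, dpi_drho) * drho_soft

        # threshold gradients: accumulate per item
        g_tau = np.zeros_like(tau)
        # row item i: d/d tau_i[c]: A[p,c,b] = dxCDF(tau_i[c], Sj_aug[b+1]) - ...
        Tj_aug = np.concatenate(
            [np.full((self.P, 1), -np.inf), Tj, np.full((self.P, 1), np.inf)], axis=1
        )
        Ti_aug = np.concatenate(
            [np.full((self.P, 1), -np.inf), Ti, np.full((self.P, 1), np.inf)], axis=1
        )
        dxg = bvn_cdf_dx(Ti[:, :, None], Tj_aug[:, None, :], rb)  # (P, m-1, m+1)
        A = np.diff(dxg, axis=2)                                  # (P, m-1, m)
        # contribution to tau_i[c]: sum_b A[p,c,b] * (W[p,c,b] - W[p,c+1,b])
        contrib_i = np.einsum("pcb,pcb->pc", A, W[:, :-1, :] - W[:, 1:, :])
        dyg = bvn_cdf_dx(Tj[:, :, None], Ti_aug[:, None, :], rb)  # symmetric swap
        B = np.diff(dyg, axis=2)
        contrib_j = np.einsum("pcb,pcb->pc", B, W[:, :, :-1].swapaxes(1, 2)
                              - W[:, :, 1:].swapaxes(1, 2))
        np.add.at(g_tau, self.I, -contrib_i)
        np.add.at(g_tau, self.J, -contrib_j)

        # chain thresholds through (first, log-gaps)
        g_ut = np.empty_like(ut)
        g_ut[:, 0] = g_tau.sum(axis=1)
        if m > 2:
            # tau_c depends on gap b for c >= b (0-based gap index b >= 1)
            rev_cum = np.cumsum(g_tau[:, ::-1], axis=1)[:, ::-1]
            g_ut[:, 1:] = rev_cum[:, 1:] * np.exp(ut[:, 1:])

        # structural chain
        if spec.is_baseline:
            g_us = g_rho * (1.0 - np.tanh(us) ** 2)
        else:
            lam, phi, _ = struct
            M = np.zeros((self.k, self.k))
            M[self.I, self.J] = g_rho
            M = M + M.T
            g_lam_full = M @ lam @ phi
            g_us = np.empty(us.size)
            nl = int(spec.loading_mask.sum())
            g_us[:nl] = g_lam_full[spec.loading_mask]
            iu = np.triu_indices(spec.q, 1)
            free = spec.phi_free[iu]
            if free.any():
                Bq = lam.T @ M @ lam
                g_phi = Bq[iu][free]
                phi_vals = np.tanh(us[nl:])
                g_us[nl:] = g_phi * (1.0 - phi_vals**2)

        return f, np.concatenate([g_ut.ravel(), g_us])

    # -- bounds and starts ------------------------------------------------

    def bounds(self):
        b = []
        for _ in range(self.k):
            b.append((-_TAU_BOUND, _TAU_BOUND))
            b.extend([(_GAP_LOG_LO, _GAP_LOG_HI)] * (self.m - 2))
        if self.spec.is_baseline:
            b.extend([(-_ATANH_BOUND, _ATANH_BOUND)] * self.P)
        else:
            nl = int(self.spec.loading_mask.sum())
            b.extend([(-_LOADING_BOUND, _LOADING_BOUND)] * nl)
            nphi = self.spec.n_structural - nl
            b.extend([(-_ATANH_BOUND, _ATANH_BOUND)] * nphi)
        return b


def _threshold_starts(dataset: OrdinalDataset, spec: FactorModelSpec):
    """Inverse-normal of cumulative marginal proportions, capped near +-6.

    Returns (tau matrix, had_empty_category flag).
    """
    counts = dataset.marginal_counts.astype(float)
    n = dataset.n
    cum = np.cumsum(counts, axis=1)[:, :-1] / n
    empty = bool(np.any(counts == 0))
    eps = 1.0 / (2.0 * n)
    cum = np.clip(cum, eps, 1.0 - eps)
    tau = ndtri(cum)
    # enforce strictly increasing rows (ties arise from empty categories)
    for i in range(tau.shape[0]):
        for c in range(1, tau.shape[1]):
            if tau[i, c] <= tau[i, c - 1]:
                tau[i, c] = tau[i, c - 1] + 1e-3
    return np.clip(tau, -_TAU_BOUND + 0.1, _TAU_BOUND - 0.1), empty


def polychoric_twostep(table: np.ndarray, tau_i: np.ndarray, tau_j: np.ndarray) -> float:
    """Coarse two-step polychoric estimate: thresholds fixed, rho by 1-D search."""
    from scipy.optimize import minimize_scalar

    table = np.asarray(table, float)
    n = table.sum()

    def nll(r):
        pi = np.maximum(cell_prob_table(r, tau_i, tau_j), PROB_FLOOR)
        return -np.sum(table * np.log(pi)) / n

    res = minimize_scalar(nll, bounds=(-0.999, 0.999), method="bounded",
                          options={"xatol": 1e-4})
    return float(res.x)


@dataclass
class FitOptions:
    gtol: float = 1e-6
    maxiter: int = 500
    floor: float = PROB_FLOOR


@dataclass
class PMLFit:
    """Result of one PML estimation."""

    spec: FactorModelSpec
    thresholds_hat: ThresholdSet
    loadings_hat: np.ndarray | None
    phi_hat: np.ndarray | None
    rho_hat: np.ndarray | None          # baseline polychorics (k x k) or None
    implied_rho_hat: np.ndarray         # k x k model-implied correlations
    objective: float                    # maximized N-scaled pairwise log-lik
    converged: bool
    iterations: int
    grad_norm: float
    N: int
    warnings_: list[str] = field(default_factory=list)

    @property
    def params(self) -> ParameterVector:
        if self.spec.is_baseline:
            return ParameterVector.pack(self.spec, self.thresholds_hat,
                                        rho=self.rho_hat)
        return ParameterVector.pack(self.spec, self.thresholds_hat,
                                    loadings=self.loadings_hat, phi=self.phi_hat)

    def to_dict(self) -> dict:
        d = {
            "model_id": self.spec.model_id,
            "objective": self.objective,
            "converged": self.converged,
            "iterations": self.iterations,
            "grad_norm": self.grad_norm,
            "N": self.N,
            "n_params": self.spec.n_params,
            "estimates": dict(zip(self.params.names, self.params.values.tolist())),
            "warnings": self.warnings_,
        }
        return d


def pairwise_loglik(dataset: OrdinalDataset, params: ParameterVector,
                    spec: FactorModelSpec) -> float:
    """N-scaled pairwise log-likelihood (constant dropped) at given parameters.

    Model cell probabilities with nonzero observed count are floored at
    1e-12 inside the log, with a warning.
    """
    obj = _PairwiseObjective(dataset, spec)
    if spec.is_baseline:
        tau, rho = params.unpack()
        us = np.arctanh(np.clip(rho[np.triu_indices(spec.k, 1)], -0.99995, 0.99995))
    else:
        tau, lam, phi = params.unpack()
        nl = int(spec.loading_mask.sum())
        iu = np.triu_indices(spec.q, 1)
        free = spec.phi_free[iu]
        us = np.concatenate([lam[spec.loading_mask],
                             np.arctanh(phi[iu][free])])
    u = np.concatenate([obj.encode_thresholds(tau.tau).ravel(), us])
    f, _ = obj.value_and_grad(u)
    if obj.floored_cells:
        warnings.warn(
            f"{obj.floored_cells} observed cells hit the probability floor",
            RuntimeWarning,
        )
    return -float(f) * dataset.n


def fit_pml(dataset: OrdinalDataset, spec: FactorModelSpec,
            options: FitOptions | None = None) -> PMLFit:
    """One-step PML fit: thresholds and structural parameters jointly.

    Non-convergence is reported on the returned fit, never raised.  Items
    with an empty observed category get their threshold start pinned near
    the +-6 cap and the fit is flagged.
    """
    options = options or FitOptions()
    obj = _PairwiseObjective(dataset, spec, floor=options.floor)
    warns: list[str] = []

    tau0, empty = _threshold_starts(dataset, spec)
    if empty:
        warns.append("empty observed category: threshold capped near +-6")
    if spec.is_baseline:
        starts = [
            polychoric_twostep(dataset.pairwise_tables[(i, j)], tau0[i], tau0[j])
            for i, j in spec.pair_indices()
        ]
        us0 = np.arctanh(np.clip(starts, -0.999, 0.999))
    else:
        nl = int(spec.loading_mask.sum())
        nphi = spec.n_structural - nl
        us0 = np.concatenate([np.full(nl, 0.5), np.full(nphi, np.arctanh(0.25))])
    u0 = np.concatenate([obj.encode_thresholds(tau0).ravel(), us0])

    res = minimize(
        obj.value_and_grad, u0, jac=True, method="L-BFGS-B",
        bounds=obj.bounds(),
        options={"maxiter": options.maxiter, "ftol": 1e-12,
                 "gtol": options.gtol, "maxcor": 30},
    )
    grad_norm = float(np.max(np.abs(res.jac)))
    converged = bool(res.success or grad_norm <= 10 * options.gtol)
    if not converged:
        warns.append(f"optimizer did not converge: {res.message}")
    if obj.floored_cells:
        warns.append(f"{obj.floored_cells} observed cells at the probability floor")

    ut, us = obj.split(res.x)
    tau_hat = ThresholdSet(obj.decode_thresholds(ut))
    if spec.is_baseline:
        rvec = np.tanh(us)
        rho_hat = np.eye(spec.k)
        rho_hat[np.triu_indices(spec.k, 1)] = rvec
        rho_hat = rho_hat + rho_hat.T - np.eye(spec.k)
        return PMLFit(spec=spec, thresholds_hat=tau_hat, loadings_hat=None,
                      phi_hat=None, rho_hat=rho_hat, implied_rho_hat=rho_hat,
                      objective=-float(res.fun) * dataset.n, converged=converged,
                      iterations=int(res.nit), grad_norm=grad_norm,
                      N=dataset.n, warnings_=warns)
    lam, phi = obj.decode_structural(us)
    R = lam @ phi @ lam.T
    if np.any(np.diag(R) >= 1.0):
        warns.append("Heywood case: communality >= 1 at the optimum")
    implied = R - np.diag(np.diag(R)) + np.eye(spec.k)
    return PMLFit(spec=spec, thresholds_hat=tau_hat, loadings_hat=lam,
                  phi_hat=phi, rho_hat=None, implied_rho_hat=implied,
                  objective=-float(res.fun) * dataset.n, converged=converged,
                  iterations=int(res.nit), grad_norm=grad_norm,
                  N=dataset.n, warnings_=warns)
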