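"""Factor-model specifications for ordinal items with underlying normal scores.

A model is a pattern of free loadings ``Lambda`` (k items x q factors), a
factor-correlation structure ``Phi`` with unit diagonal, and one set of
``m - 1`` free thresholds per item.  The latent response scores are
standardized (zero mean, unit variance), so the model-implied covariance of
the underlying scores is a correlation matrix: unit diagonal, off-diagonals
from Lambda Phi Lambda'.

The *baseline* model has no factor structure at all: it parameterizes every
one of the k(k-1)/2 latent (polychoric) correlations directly, plus all
thresholds.  Its fit is a test of underlying multivariate normality itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
from typing import Iterator

import numpy as np

__all__ = [
    "InvalidParameterError",
    "ThresholdSet",
    "FactorModelSpec",
    "ParameterVector",
    "implied_correlations",
    "study_model",
]


class InvalidParameterError(ValueError):
    """Parameter values outside the admissible region of the model."""


@dataclass(frozen=True)
class ThresholdSet:
    """Cut-points on the standard-normal scale, one row per item.

    ``tau`` has shape (k, m-1) and must be strictly increasing within each
    row.  The boundary thresholds -inf and +inf are implicit.
    """

    tau: np.ndarray

    def __post_init__(self):
        tau = np.atleast_2d(np.asarray(self.tau, float))
        if not np.all(np.isfinite(tau)):
            raise InvalidParameterError("thresholds must be finite")
        if tau.shape[1] >= 2 and not np.all(np.diff(tau, axis=1) > 0):
            raise InvalidParameterError("thresholds must increase within each item")
        object.__setattr__(self, "tau", tau)

    @property
    def k(self) -> int:
        return self.tau.shape[0]

    @property
    def m(self) -> int:
        return self.tau.shape[1] + 1

    def augmented(self) -> np.ndarray:
        """(k, m+1) array with -inf / +inf boundary columns attached."""
        k = self.tau.shape[0]
        neg = np.full((k, 1), -np.inf)
        pos = np.full((k, 1), np.inf)
        return np.hstack([neg, self.tau, pos])

    def interval_probs(self) -> np.ndarray:
        """(k, m) expected category proportions under the standard normal."""
        from scipy.special import ndtr

        aug = self.augmented()
        cdf = np.where(np.isneginf(aug), 0.0, np.where(np.isposinf(aug), 1.0, 0.0))
        fin = np.isfinite(aug)
        cdf[fin] = ndtr(aug[fin])
        return np.diff(cdf, axis=1)


def _pairs(k: int) -> Iterator[tuple[int, int]]:
    for i in range(k - 1):
        for j in range(i + 1, k):
            yield i, j


@dataclass(frozen=True)
class FactorModelSpec:
    """Loading pattern and factor-correlation structure of one model.

    For ``model_id == "baseline"`` the spec has ``q = 0`` and the structural
    parameters are the k(k-1)/2 polychoric correlations themselves.
    """

    k: int
    m: int
    model_id: str = "custom"
    loading_mask: np.ndarray = field(default=None)
    phi_free: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.m < 2:
            raise ValueError("need at least two response categories")
        mask = self.loading_mask
        if mask is None:
            mask = np.zeros((self.k, 0), bool)
        mask = np.asarray(mask, bool)
        if mask.shape[0] != self.k:
            raise ValueError("loading_mask must have one row per item")
        object.__setattr__(self, "loading_mask", mask)
        q = mask.shape[1]
        pf = self.phi_free
        if pf is None:
            pf = np.zeros((q, q), bool)
        pf = np.asarray(pf, bool)
        pf = pf | pf.T
        np.fill_diagonal(pf, False)  # diagonal of Phi fixed at unity
        if pf.shape != (q, q):
            raise ValueError("phi_free must be q x q")
        object.__setattr__(self, "phi_free", pf)
        if self.model_id != "baseline":
            if q == 0 or not mask.any(axis=1).all():
                raise ValueError("every item needs at least one free loading")

    @property
    def q(self) -> int:
        return self.loading_mask.shape[1]

    @property
    def is_baseline(self) -> bool:
        return self.model_id == "baseline"

    @property
    def n_thresholds(self) -> int:
        return self.k * (self.m - 1)

    @property
    def n_structural(self) -> int:
        """Free parameters excluding thresholds."""
        if self.is_baseline:
            return self.k * (self.k - 1) // 2
        n_phi = int(np.count_nonzero(np.triu(self.phi_free, 1)))
        return int(self.loading_mask.sum()) + n_phi

    @property
    def n_params(self) -> int:
        """Total free-parameter count n entering all degrees of freedom."""
        return self.n_structural + self.n_thresholds

    def pair_indices(self) -> list[tuple[int, int]]:
        return list(_pairs(self.k))

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d = {"k": self.k, "m": self.m, "model_id": self.model_id}
        if not self.is_baseline and self.model_id == "custom":
            d["loading_mask"] = self.loading_mask.astype(int).tolist()
            d["phi_free"] = self.phi_free.astype(int).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FactorModelSpec":
        model_id = d.get("model_id", "custom")
        if model_id in ("baseline", "one_factor", "two_factor"):
            return study_model(model_id, k=int(d["k"]), m=int(d["m"]))
        return cls(
            k=int(d["k"]),
            m=int(d["m"]),
            model_id="custom",
            loading_mask=np.asarray(d["loading_mask"], bool),
            phi_free=np.asarray(d.get("phi_free"), bool)
            if d.get("phi_free") is not None
            else None,
        )

    @classmethod
    def from_file(cls, path) -> "FactorModelSpec":
        text = open(path).read()
        try:
            d = json.loads(text)
        except json.JSONDecodeError:
            import yaml

            d = yaml.safe_load(text)
        return cls.from_dict(d)


def study_model(model_id: str, k: int = 6, m: int = 2) -> FactorModelSpec:
    """The three models of the simulation design.

    * ``baseline`` — all k(k-1)/2 polychoric correlations and all
      thresholds free; no factor structure.
    * ``one_factor`` — a free k x 1 loading matrix, factor variance fixed
      at unity.
    * ``two_factor`` — for k = 6 the generating pattern: items 1-4 load on
      factor 1, items 4-6 on factor 2 (item 4 cross-loads), 7 free loadings
      in total, plus one free factor correlation.
    """
    if model_id == "baseline":
        return FactorModelSpec(k=k, m=m, model_id="baseline")
    if model_id == "one_factor":
        mask = np.ones((k, 1), bool)
        return FactorModelSpec(k=k, m=m, model_id="one_factor", loading_mask=mask)
    if model_id == "two_factor":
        if k != 6:
            raise ValueError("the study's two-factor pattern is defined for k = 6")
        mask = np.zeros((6, 2), bool)
        mask[0:4, 0] = True   # items 1-4 on factor 1
        mask[3:6, 1] = True   # items 4-6 on factor 2; item 4 cross-loads
        phi_free = np.array([[False, True], [True, False]])
        return FactorModelSpec(
            k=6, m=m, model_id="two_factor", loading_mask=mask, phi_free=phi_free
        )
    raise ValueError(f"unknown model_id: {model_id!r}")


def implied_correlations(
    spec: FactorModelSpec, loadings: np.ndarray, phi: np.ndarray
) -> np.ndarray:
    """Model-implied correlation matrix Lambda Phi Lambda' with unit diagonal.

    Residual variances are Theta = I - diag(Lambda Phi Lambda'), so the
    communalities diag(Lambda Phi Lambda') must be below one.
    """
    loadings = np.asarray(loadings, float)
    phi = np.asarray(phi, float)
    if loadings.shape != spec.loading_mask.shape:
        raise ValueError("loadings shape does not match the spec")
    if np.any(loadings[~spec.loading_mask] != 0.0):
        raise InvalidParameterError("nonzero loading outside the free pattern")
    if phi.shape != (spec.q, spec.q) or not np.allclose(np.diag(phi), 1.0):
        raise InvalidParameterError("phi must be a correlation matrix (unit diagonal)")
    lpl = loadings @ phi @ loadings.T
    comm = np.diag(lpl)
    if np.any(comm >= 1.0):
        raise InvalidParameterError(
            f"communality >= 1 (max {comm.max():.4f}): negative residual variance"
        )
    rho = lpl - np.diag(comm) + np.eye(spec.k)
    return (rho + rho.T) / 2.0


class ParameterVector:
    """Flat free-parameter vector with a name <-> index map.

    Layout: thresholds item by item (tau[i,1] .. tau[i,m-1]), then the
    structural block — free loadings in row-major mask order and free upper
    off-diagonal Phi entries for factor models, or the polychoric
    correlations rho_ij (i < j lexicographic) for the baseline.
    Round-tripping through :meth:`pack` / :meth:`unpack` is the identity.
    """

    def __init__(self, spec: FactorModelSpec, values: np.ndarray):
        values = np.asarray(values, float)
        if values.shape != (spec.n_params,):
            raise ValueError(
                f"expected {spec.n_params} parameters, got {values.shape}"
            )
        self.spec = spec
        self.values = values
        self.names = parameter_names(spec)
        self._index = {n: i for i, n in enumerate(self.names)}

    def __getitem__(self, name: str) -> float:
        return float(self.values[self._index[name]])

    def index(self, name: str) -> int:
        return self._index[name]

    # -- pack / unpack ----------------------------------------------------

    @classmethod
    def pack(
        cls,
        spec: FactorModelSpec,
        thresholds: ThresholdSet,
        loadings: np.ndarray | None = None,
        phi: np.ndarray | None = None,
        rho: np.ndarray | None = None,
    ) -> "ParameterVector":
        parts = [thresholds.tau.ravel()]
        if spec.is_baseline:
            rho = np.asarray(rho, float)
            rvec = rho[np.triu_indices(spec.k, 1)] if rho.ndim == 2 else rho
            if np.any(np.abs(rvec) >= 1.0):
                raise InvalidParameterError("polychoric correlations must lie in (-1, 1)")
            parts.append(rvec)
        else:
            loadings = np.asarray(loadings, float)
            parts.append(loadings[spec.loading_mask])
            iu = np.triu_indices(spec.q, 1)
            free = spec.phi_free[iu]
            pvec = np.asarray(phi, float)[iu][free]
            if np.any(np.abs(pvec) >= 1.0):
                raise InvalidParameterError("factor correlations must lie in (-1, 1)")
            parts.append(pvec)
        return cls(spec, np.concatenate(parts))

    def unpack(self):
        """-> (ThresholdSet, loadings, phi) or (ThresholdSet, rho matrix)."""
        spec = self.spec
        nt = spec.n_thresholds
        tau = ThresholdSet(self.values[:nt].reshape(spec.k, spec.m - 1))
        rest = self.values[nt:]
        if spec.is_baseline:
            rho = np.eye(spec.k)
            iu = np.triu_indices(spec.k, 1)
            rho[iu] = rest
            rho = rho + rho.T - np.eye(spec.k)
            return tau, rho
        nl = int(spec.loading_mask.sum())
        loadings = np.zeros(spec.loading_mask.shape)
        loadings[spec.loading_mask] = rest[:nl]
        phi = np.eye(spec.q)
        iu = np.triu_indices(spec.q, 1)
        free = spec.phi_free[iu]
        vals = np.zeros(free.sum())
        vals[:] = rest[nl:]
        full = np.zeros(len(free))
        full[free] = vals
        phi[iu] = full
        phi = phi + phi.T - np.diag(np.diag(phi))
        return tau, loadings, phi


def parameter_names(spec: FactorModelSpec) -> list[str]:
    names = [
        f"tau[{i + 1},{c + 1}]"
        for i in range(spec.k)
        for c in range(spec.m - 1)
    ]
    if spec.is_baseline:
        names += [f"rho[{i + 1},{j + 1}]" for i, j in _pairs(spec.k)]
    else:
        names += [
            f"lambda[{i + 1},{q + 1}]"
            for i in range(spec.k)
            for q in range(spec.q)
            if spec.loading_mask[i, q]
        ]
        iu = zip(*np.triu_indices(spec.q, 1))
        names += [
            f"phi[{a + 1},{b + 1}]" for a, b in iu if spec.phi_free[a, b]
        ]
    return names
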