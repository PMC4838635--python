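"""Ordinal data generation from a latent multivariate-normal population.

Continuous scores are drawn from N(0, Sigma) with Sigma the unit-diagonal
matrix implied by the population two-factor model, then discretized at fixed
thresholds shared by all items:

* 2 categories — threshold 0 (expected proportions 0.50 / 0.50);
* 3 categories — thresholds -0.6, 0.6 (0.27 / 0.45 / 0.27);
* 4 categories — thresholds -1.2, 0, 1.2 (0.11 / 0.39 / 0.39 / 0.11).

A latent score exactly equal to a threshold belongs to the lower category
(the interval rule is tau_{x-1} < x* <= tau_x).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import pandas as pd

from .models import (
    FactorModelSpec,
    ThresholdSet,
    implied_correlations,
    study_model,
)

__all__ = [
    "POPULATION_LOADINGS",
    "POPULATION_PHI",
    "population_correlations",
    "study_thresholds",
    "GenerationConfig",
    "OrdinalDataset",
    "generate",
]

# Population two-factor model: items 1-4 on factor 1, items 4-6 on factor 2,
# item 4 cross-loading, factor correlation 0.5.
POPULATION_LOADINGS = np.array(
    [
        [0.9, 0.0],
        [0.8, 0.0],
        [0.7, 0.0],
        [0.5, 0.6],
        [0.0, 0.7],
        [0.0, 0.8],
    ]
)
POPULATION_PHI = np.array([[1.0, 0.5], [0.5, 1.0]])

_STUDY_TAUS = {2: [0.0], 3: [-0.6, 0.6], 4: [-1.2, 0.0, 1.2]}


def population_correlations() -> np.ndarray:
    """Unit-diagonal Sigma = Lambda Phi Lambda' + Theta of the population model."""
    spec = study_model("two_factor", k=6, m=2)
    return implied_correlations(spec, POPULATION_LOADINGS, POPULATION_PHI)


def study_thresholds(m: int, k: int = 6) -> ThresholdSet:
    """The study's fixed cut-points, identical for all k items."""
    if m not in _STUDY_TAUS:
        raise ValueError(f"unsupported category count m={m}; study uses m in {{2,3,4}}")
    row = np.asarray(_STUDY_TAUS[m], float)
    return ThresholdSet(np.tile(row, (k, 1)))


@dataclass(frozen=True)
class GenerationConfig:
    """One simulated sample: size, categories, thresholds, population, seed."""

    n: int
    m: int
    seed: int
    thresholds: ThresholdSet | None = None
    loadings: np.ndarray = field(default=None)
    phi: np.ndarray = field(default=None)
    corr: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be at least 1")
        if self.m < 2:
            raise ValueError("m must be at least 2")
        if self.thresholds is None:
            object.__setattr__(self, "thresholds", study_thresholds(self.m))
        if self.thresholds.m != self.m:
            raise ValueError("thresholds inconsistent with m")
        if self.corr is None:
            if self.loadings is None:
                object.__setattr__(self, "loadings", POPULATION_LOADINGS)
                object.__setattr__(self, "phi", POPULATION_PHI)
            lam = np.asarray(self.loadings, float)
            spec = FactorModelSpec(
                k=lam.shape[0],
                m=self.m,
                model_id="custom",
                loading_mask=lam != 0.0,
                phi_free=np.ones((lam.shape[1],) * 2, bool),
            )
            object.__setattr__(
                self, "corr", implied_correlations(spec, lam, np.asarray(self.phi, float))
            )

    @property
    def k(self) -> int:
        return self.corr.shape[0]


@dataclass(frozen=True)
class OrdinalDataset:
    """Integer response codes in 1..m plus cached pairwise and pattern counts."""

    codes: np.ndarray
    m: int

    def __post_init__(self):
        codes = np.asarray(self.codes)
        if codes.ndim != 2:
            raise ValueError("codes must be an n x k matrix")
        if codes.min() < 1 or codes.max() > self.m:
            raise ValueError("codes must lie in 1..m")
        object.__setattr__(self, "codes", np.ascontiguousarray(codes, dtype=np.int64))

    @property
    def n(self) -> int:
        return self.codes.shape[0]

    @property
    def k(self) -> int:
        return self.codes.shape[1]

    @cached_property
    def pairwise_tables(self) -> dict[tuple[int, int], np.ndarray]:
        """m x m contingency table of counts for every item pair i < j (0-based)."""
        m, k = self.m, self.k
        z = self.codes - 1
        out = {}
        for i in range(k - 1):
            for j in range(i + 1, k):
                flat = z[:, i] * m + z[:, j]
                out[(i, j)] = np.bincount(flat, minlength=m * m).reshape(m, m)
        return out

    @cached_property
    def pattern_counts(self) -> dict[tuple[int, ...], int]:
        """Observed full response patterns (1-based tuples) and their counts."""
        uniq, counts = np.unique(self.codes, axis=0, return_counts=True)
        return {tuple(int(v) for v in row): int(c) for row, c in zip(uniq, counts)}

    @property
    def u_r(self) -> int:
        """Number of distinct observed response patterns."""
        return len(self.pattern_counts)

    @cached_property
    def marginal_counts(self) -> np.ndarray:
        """(k, m) per-item category counts."""
        return np.stack(
            [np.bincount(self.codes[:, i] - 1, minlength=self.m) for i in range(self.k)]
        )

    # -- CSV round trip ---------------------------------------------------

    def to_csv(self, path_or_buf) -> None:
        df = pd.DataFrame(
            self.codes, columns=[f"item{i + 1}" for i in range(self.k)]
        )
        df.to_csv(path_or_buf, index=False)

    @classmethod
    def from_csv(cls, path_or_buf, m: int | None = None) -> "OrdinalDataset":
        df = pd.read_csv(path_or_buf)
        codes = df.to_numpy(dtype=np.int64)
        return cls(codes=codes, m=int(codes.max()) if m is None else m)


def generate(config: GenerationConfig) -> OrdinalDataset:
    """Draw latent scores from N(0, corr) and discretize at the thresholds.

    Reproducible for a given seed; degenerate samples (an item with an empty
    category) are retained as drawn — redrawing would bias rejection rates.
    """
    corr = np.asarray(config.corr, float)
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise ValueError("population correlation matrix is not positive definite") from exc
    rng = np.random.default_rng(config.seed)
    latent = rng.standard_normal((config.n, corr.shape[0])) @ chol.T
    codes = np.empty_like(latent, dtype=np.int64)
    aug_tau = config.thresholds.tau
    for i in range(corr.shape[0]):
        # side='left': a score equal to a cut-point falls in the lower category
        codes[:, i] = np.searchsorted(aug_tau[i], latent[:, i], side="left") + 1
    return OrdinalDataset(codes=codes, m=config.m)
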