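"""Ground-truth Gaussian graphical models, Gaussian data, and the
data-level view of shrinkage.

Networks are built GeneNet-style: a random sparse support is drawn
uniformly over variable pairs, precision off-diagonals are sampled from a
symmetric effect-size law, and the diagonal is set to one plus the
absolute row sum, which guarantees strict diagonal dominance and hence
positive definiteness. Standardizing the resulting precision yields the
population partial correlations; with the default effect range the median
nonzero |pcor| is about 0.3.

Shrinking the model is equivalent to shrinking the data: replacing the
singular values s_k of a standardized data matrix by
sqrt((n-1) * ((1-lambda) s_k^2/(n-1) + lambda)) produces a dataset whose
sample correlation is exactly (1-lambda) R + lambda I.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamatrix import DataMatrix
from .shrinkage import partial_correlation_from_precision

__all__ = [
    "GGMTruth",
    "SimulationConfig",
    "simulate_network",
    "simulate_data",
    "shrink_data",
    "concatenation_experiment",
]

DEFAULT_EFFECT_RANGE = (0.25, 0.75)


@dataclass
class GGMTruth:
    """A ground-truth GGM: support, precision and population pcors."""

    p: int
    adjacency: np.ndarray               # boolean, symmetric, zero diagonal
    pcor_true: np.ndarray               # population partial correlations
    precision: np.ndarray               # positive definite
    frac_nonzero: float
    seed: int

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum() // 2)

    @property
    def covariance(self) -> np.ndarray:
        return np.linalg.inv(self.precision)


@dataclass
class SimulationConfig:
    """Benchmark design: problem sizes, replication and effect sizes."""

    p: int = 100
    n_values: tuple[int, ...] = (10, 20, 30, 40, 50, 60, 70, 80, 90, 100)
    frac_nonzero: float = 0.01
    n_replicates: int = 25
    seed: int = 0
    lambda_grid: np.ndarray | None = None
    effect_range: tuple[float, float] = DEFAULT_EFFECT_RANGE

    def __post_init__(self) -> None:
        if self.p < 3 or self.n_replicates < 1 or min(self.n_values) < 2:
            raise ValueError("invalid simulation configuration")


def simulate_network(
    p: int,
    frac_nonzero: float,
    seed: int,
    effect_range: tuple[float, float] = DEFAULT_EFFECT_RANGE,
) -> GGMTruth:
    """Draw a random sparse GGM with the requested edge density."""
    if p < 3:
        raise ValueError("need at least 3 nodes")
    if not 0.0 <= frac_nonzero < 1.0:
        raise ValueError("frac_nonzero must be in [0, 1)")
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(p, 1)
    n_pairs = iu[0].size
    n_edges = int(round(frac_nonzero * n_pairs))
    chosen = rng.choice(n_pairs, size=n_edges, replace=False)
    omega = np.zeros((p, p))
    magnitudes = rng.uniform(*effect_range, size=n_edges)
    signs = rng.choice([-1.0, 1.0], size=n_edges)
    omega[iu[0][chosen], iu[1][chosen]] = magnitudes * signs
    omega = omega + omega.T
    np.fill_diagonal(omega, 1.0 + np.abs(omega).sum(axis=1))
    if np.linalg.eigvalsh(omega).min() <= 0:  # cannot happen under dominance
        raise RuntimeError("generated precision is not positive definite")
    adjacency = np.zeros((p, p), dtype=bool)
    adjacency[iu[0][chosen], iu[1][chosen]] = True
    adjacency |= adjacency.T
    pcor = partial_correlation_from_precision(omega).values
    off = ~np.eye(p, dtype=bool)
    pcor[off & ~adjacency] = 0.0        # exact zeros off the support
    return GGMTruth(
        p=p,
        adjacency=adjacency,
        pcor_true=pcor,
        precision=omega,
        frac_nonzero=frac_nonzero,
        seed=seed,
    )


def simulate_data(truth: GGMTruth, n: int, seed: int) -> DataMatrix:
    """Draw ``n`` i.i.d. multivariate-normal samples from the truth."""
    if n < 2:
        raise ValueError("need at least 2 samples")
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(truth.covariance)
    values = rng.standard_normal((n, truth.p)) @ chol.T
    names = [f"G{j + 1}" for j in range(truth.p)]
    return DataMatrix(values, names)


def shrink_data(data: DataMatrix, lam: float) -> DataMatrix:
    """Data-level shrinkage via the singular value decomposition.

    For standardized data with n > p this reproduces model-level
    shrinkage exactly: the sample covariance of the result equals
    (1 - lambda) R + lambda I. For n <= p only the representable
    (nonzero) spectrum can be shrunk.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"shrinkage intensity must be in [0, 1], got {lam}")
    if not data.standardized:
        raise ValueError("shrink_data requires standardized data")
    n = data.n
    U, s, Vt = np.linalg.svd(data.values, full_matrices=False)
    alpha = s**2 / (n - 1.0)
    s_shrunk = np.sqrt((n - 1.0) * ((1.0 - lam) * alpha + lam))
    values = (U * s_shrunk) @ Vt
    return DataMatrix(values, list(data.variable_names), standardized=False)


def concatenation_experiment(data: DataMatrix) -> tuple[DataMatrix, DataMatrix]:
    """Return ``data`` and its row-duplicated copy.

    Both datasets carry the same sample correlation, but the doubled
    sample size changes the optimal shrinkage intensity; comparable
    estimators must give near-identical results on the pair.
    """
    doubled = DataMatrix(
        np.vstack([data.values, data.values]),
        list(data.variable_names),
        standardized=False,
    )
    return data, doubled
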