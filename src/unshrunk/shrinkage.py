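"""Correlation estimation, linear (Ledoit-Wolf-style) shrinkage and shrunk
partial correlations.

The estimators operate on the correlation scale: the sample correlation
R is shrunk towards the identity target,

    R(lambda) = (1 - lambda) R + lambda I,        0 <= lambda <= 1,

which leaves the eigenvectors of R untouched and maps each eigenvalue
``a`` to ``(1 - lambda) a + lambda``. Partial correlations are obtained by
standardizing the negated inverse (precision) matrix,

    P_ij = -Omega_ij / sqrt(Omega_ii Omega_jj),   Omega = R(lambda)^{-1},

computed through the eigendecomposition so that a single factorization of
R serves every shrinkage value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamatrix import DataMatrix

__all__ = [
    "ShrinkageModel",
    "PartialCorrelationMatrix",
    "sample_correlation",
    "estimate_optimal_lambda",
    "shrink_correlation",
    "partial_correlation_from_precision",
    "shrunk_partial_correlation",
    "condition_number",
]

#: relative threshold below which an eigenvalue counts as numerically zero
_ZERO_EIG_RTOL = 1e-8
#: relative tolerance for clamping small negative round-off eigenvalues
_NEG_EIG_RTOL = 1e-10


@dataclass
class PartialCorrelationMatrix:
    """Symmetric p x p matrix of partial correlations.

    ``lam`` records the shrinkage the matrix was computed at; ``lam == 0``
    encodes a classical / un-shrunk estimate.
    """

    values: np.ndarray
    lam: float
    variable_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        p = self.values.shape[0]
        if self.values.shape != (p, p):
            raise ValueError("partial correlation matrix must be square")
        if not self.variable_names:
            self.variable_names = [f"V{j + 1}" for j in range(p)]

    @property
    def p(self) -> int:
        return self.values.shape[0]

    def offdiag(self) -> np.ndarray:
        """Upper-triangular (i < j) entries as a flat vector."""
        iu = np.triu_indices(self.p, 1)
        return self.values[iu]


@dataclass
class ShrinkageModel:
    """Sample correlation with its eigendecomposition and shrinkage state.

    ``eigenvalues`` are those of the *sample* correlation, sorted
    descending; ``R_shrunk`` is populated by :func:`shrink_correlation`.
    """

    R_sample: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    variable_names: list[str]
    lam: float | None = None
    R_shrunk: np.ndarray | None = None
    n_samples: int | None = None

    @property
    def p(self) -> int:
        return self.R_sample.shape[0]

    def shrunk_eigenvalues(self, lam: float) -> np.ndarray:
        """Eigenvalues of R(lambda): ``(1 - lam) a_k + lam``."""
        return (1.0 - lam) * self.eigenvalues + lam

    def is_singular(self, rtol: float = _ZERO_EIG_RTOL) -> bool:
        amax = self.eigenvalues.max()
        return bool(self.eigenvalues.min() < rtol * amax)


def _sorted_eigh(R: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Descending eigendecomposition with a reproducible sign convention.

    Tiny negative eigenvalues from round-off are clamped to zero; anything
    more negative indicates an invalid correlation matrix and raises.
    """
    vals, vecs = np.linalg.eigh(R)
    vals, vecs = vals[::-1], vecs[:, ::-1]
    amax = float(vals.max())
    tol = _NEG_EIG_RTOL * max(amax, 1.0)
    neg = vals < -tol
    if neg.any():
        raise np.linalg.LinAlgError(
            f"eigenvalue {vals[neg].min():.3e} is too negative for round-off"
        )
    vals = np.where(vals < 0, 0.0, vals)
    # first nonzero component of each eigenvector made positive
    for k in range(vecs.shape[1]):
        col = vecs[:, k]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            vecs[:, k] = -col
    return vals, vecs


def sample_correlation(data: DataMatrix) -> ShrinkageModel:
    """Fit the sample correlation of ``data`` and eigendecompose it.

    Works for any ``n >= 2`` including the singular ``n <= p`` case.
    """
    std = data.standardize()  # raises on zero-variance columns
    R = np.corrcoef(std.values, rowvar=False)
    R = (R + R.T) / 2.0
    np.fill_diagonal(R, 1.0)
    vals, vecs = _sorted_eigh(R)
    return ShrinkageModel(
        R_sample=R,
        eigenvalues=vals,
        eigenvectors=vecs,
        variable_names=list(data.variable_names),
        n_samples=data.n,
    )


def estimate_optimal_lambda(data: DataMatrix) -> float:
    """Analytic mean-squared-error optimal shrinkage intensity.

    Schaefer-Strimmer estimator for shrinking a correlation matrix towards
    the identity:

        lambda* = sum_{i<j} var_hat(r_ij) / sum_{i<j} r_ij^2,

    clipped to [0, 1], with ``var_hat(r_ij)`` the unbiased variance
    estimate of the sample correlation built from the centred
    cross-product terms w_kij = x_ki x_kj of the standardized data.
    """
    if data.n < 3:
        raise ValueError("need n >= 3 to estimate the variance of correlations")
    X = data.standardize().values
    n, p = X.shape
    M1 = X.T @ X / n                       # mean of w over samples
    M2 = (X**2).T @ (X**2) / n             # mean of w^2
    r = n / (n - 1.0) * M1
    var_r = n**2 / (n - 1.0) ** 3 * (M2 - M1**2)
    iu = np.triu_indices(p, 1)
    denom = float((r[iu] ** 2).sum())
    if denom == 0.0:
        return 1.0
    return float(np.clip(var_r[iu].sum() / denom, 0.0, 1.0))


def shrink_correlation(model: ShrinkageModel, lam: float) -> ShrinkageModel:
    """Convex shrinkage of the sample correlation towards the identity."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"shrinkage intensity must be in [0, 1], got {lam}")
    R_shrunk = (1.0 - lam) * model.R_sample + lam * np.eye(model.p)
    return ShrinkageModel(
        R_sample=model.R_sample,
        eigenvalues=model.eigenvalues,
        eigenvectors=model.eigenvectors,
        variable_names=list(model.variable_names),
        lam=lam,
        R_shrunk=R_shrunk,
        n_samples=model.n_samples,
    )


def partial_correlation_from_precision(
    Omega: np.ndarray, variable_names: list[str] | None = None, lam: float = 0.0
) -> PartialCorrelationMatrix:
    """Standardize a precision matrix into partial correlations."""
    Omega = np.asarray(Omega, dtype=float)
    if not np.allclose(Omega, Omega.T, atol=1e-8 * max(1.0, np.abs(Omega).max())):
        raise ValueError("precision matrix must be symmetric")
    d = np.diag(Omega)
    if (d <= 0).any():
        j = int(np.flatnonzero(d <= 0)[0])
        raise ValueError(f"non-positive precision diagonal at index {j}")
    root = np.sqrt(d)
    P = -Omega / np.outer(root, root)
    np.fill_diagonal(P, 1.0)
    P = (P + P.T) / 2.0
    return PartialCorrelationMatrix(P, lam=lam, variable_names=list(variable_names or []))


def shrunk_partial_correlation(model: ShrinkageModel, lam: float) -> PartialCorrelationMatrix:
    """Partial correlations of the shrunk correlation R(lambda).

    Uses the eigen route ``Omega = V diag(1 / a(lambda)) V^t`` rather than a
    dense inverse; ``lam = 0`` is allowed only for nonsingular R.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"shrinkage intensity must be in [0, 1], got {lam}")
    alpha = model.shrunk_eigenvalues(lam)
    if lam == 0.0 and model.is_singular():
        raise np.linalg.LinAlgError(
            "sample correlation is singular at lambda=0; use the unshrink "
            "module (analytic_unshrunk_limit / spline_unshrink) instead"
        )
    Omega = (model.eigenvectors / alpha) @ model.eigenvectors.T
    return partial_correlation_from_precision(Omega, model.variable_names, lam=lam)


def condition_number(model: ShrinkageModel, lam: float | None = None) -> float:
    """Ratio of the largest to smallest eigenvalue magnitude.

    Evaluated for the sample correlation, or for R(lambda) when ``lam`` is
    given. Returns ``inf`` for a numerically singular matrix.
    """
    alpha = model.eigenvalues if lam is None else model.shrunk_eigenvalues(lam)
    amax = float(np.abs(alpha).max())
    amin = float(np.abs(alpha).min())
    if amin <= _ZERO_EIG_RTOL * amax:
        return float("inf")
    return amax / amin
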