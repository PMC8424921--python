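"""The un-shrunk partial correlation: the limit of the shrunk estimate as
the shrinkage intensity approaches zero.

Two routes are provided.

* **Analytic limit.** For a nonsingular sample correlation the limit is the
  classical partial correlation. For a singular one, write the shrunk
  precision as (1/lambda) V diag(lambda / a(lambda)) V^t; the diagonal
  factors tend to 1 on the null eigenspace and to 0 elsewhere, so after
  the 1/lambda prefactor cancels in the standardized ratio the limit is

      P0_ij = -M_ij / sqrt(M_ii M_jj),   M = V0 V0^t,

  with V0 the orthonormal basis of the null space of R. The limit is
  degenerate when some M_ii = 0 (variable orthogonal to the null space).

* **Spline extrapolation.** The practical route for real data, where
  round-off blurs the null space: compute shrunk partial correlations on a
  grid of lambda values, Fisher-transform them, fit a weighted cubic
  smoothing spline per edge (weights = reciprocal condition number of the
  shrunk correlation, so ill-conditioned small-lambda points count less)
  and extrapolate the fit to lambda = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import make_smoothing_spline

from .datamatrix import DataMatrix
from .shrinkage import (
    PartialCorrelationMatrix,
    ShrinkageModel,
    _ZERO_EIG_RTOL,
    partial_correlation_from_precision,
    sample_correlation,
    estimate_optimal_lambda,
    shrunk_partial_correlation,
)

__all__ = [
    "LambdaProfile",
    "UnshrunkResult",
    "fisher_z",
    "inverse_fisher_z",
    "default_lambda_grid",
    "lambda_profile",
    "analytic_unshrunk_limit",
    "spline_unshrink",
    "unshrunk_partial_correlation",
]

#: candidate smoothing penalties scanned by generalized cross-validation
_PENALTY_GRID = np.logspace(-8.0, 2.0, 41)
#: clamp for back-transformed values that fall outside the open unit interval
_CLAMP = 1.0 - 1e-12
#: largest p for which the 'auto' mode attempts the analytic route
DEFAULT_ANALYTIC_CAP = 25


def fisher_z(r):
    """Fisher transformation z = atanh(r); requires |r| < 1."""
    r = np.asarray(r, dtype=float)
    if (np.abs(r) >= 1.0).any():
        raise ValueError("Fisher transform requires |r| < 1")
    return np.arctanh(r) if r.ndim else float(np.arctanh(r))


def inverse_fisher_z(z):
    """Inverse Fisher transformation r = tanh(z)."""
    z = np.asarray(z, dtype=float)
    return np.tanh(z) if z.ndim else float(np.tanh(z))


def default_lambda_grid(num: int = 21, lo: float = 0.05, hi: float = 0.95) -> np.ndarray:
    """Evenly spaced, data-independent lambda grid on [lo, hi].

    Keeping the grid independent of the data makes un-shrunk estimates of
    datasets with identical sample correlation identical by construction,
    which is the comparability property the estimator is for.
    """
    return np.linspace(lo, hi, num)


@dataclass
class LambdaProfile:
    """Shrunk partial correlations of every edge along a lambda grid."""

    lambdas: np.ndarray                 # (m,) strictly increasing, in (0,1)
    pcor_values: np.ndarray             # (m, E) one column per i<j edge
    z_values: np.ndarray                # Fisher-transformed copy
    weights: np.ndarray                 # (m,) reciprocal condition numbers
    optimal_lambda: float | None
    variable_names: list[str] = field(default_factory=list)

    @property
    def p(self) -> int:
        return len(self.variable_names)

    @property
    def n_edges(self) -> int:
        return self.pcor_values.shape[1]


@dataclass
class UnshrunkResult:
    """Un-shrunk partial correlation matrix plus fit diagnostics."""

    P0: PartialCorrelationMatrix
    method: str                         # 'analytic_limit' | 'spline_extrapolation'
    diagnostics: dict = field(default_factory=dict)


def lambda_profile(
    model: ShrinkageModel,
    grid: np.ndarray | None = None,
    optimal_lambda: float | None = None,
) -> LambdaProfile:
    """Evaluate shrunk partial correlations and weights along ``grid``."""
    grid = default_lambda_grid() if grid is None else np.sort(np.unique(np.asarray(grid, float)))
    if grid.size < 4:
        raise ValueError("lambda grid needs at least 4 points")
    if grid.min() <= 0.0 or grid.max() >= 1.0:
        raise ValueError("lambda grid must lie strictly inside (0, 1)")
    p = model.p
    iu = np.triu_indices(p, 1)
    pcors = np.empty((grid.size, iu[0].size))
    weights = np.empty(grid.size)
    for k, lam in enumerate(grid):
        pcors[k] = shrunk_partial_correlation(model, float(lam)).values[iu]
        alpha = model.shrunk_eigenvalues(float(lam))
        weights[k] = alpha.min() / alpha.max()
    z = np.arctanh(np.clip(pcors, -_CLAMP, _CLAMP))
    if not np.isfinite(z).all():
        bad = np.argwhere(~np.isfinite(z))[0]
        raise ValueError(
            f"non-finite Fisher z for edge ({iu[0][bad[1]]}, {iu[1][bad[1]]})"
        )
    return LambdaProfile(
        lambdas=grid,
        pcor_values=pcors,
        z_values=z,
        weights=weights,
        optimal_lambda=optimal_lambda,
        variable_names=list(model.variable_names),
    )


def analytic_unshrunk_limit(model: ShrinkageModel) -> UnshrunkResult:
    """Closed-form lambda -> 0 limit from the eigendecomposition."""
    alpha, V = model.eigenvalues, model.eigenvectors
    zero = alpha < _ZERO_EIG_RTOL * alpha.max()
    if not zero.any():
        P0 = shrunk_partial_correlation(model, 0.0)
        return UnshrunkResult(P0=P0, method="analytic_limit",
                              diagnostics={"null_dimension": 0})
    V0 = V[:, zero]
    M = V0 @ V0.T                       # orthogonal projector onto null(R)
    d = np.diag(M)
    if (d <= 1e-12).any():
        j = int(np.flatnonzero(d <= 1e-12)[0])
        raise np.linalg.LinAlgError(
            f"degenerate limit: variable {model.variable_names[j]!r} is "
            "orthogonal to the null space; use spline_unshrink"
        )
    P0 = partial_correlation_from_precision(M, model.variable_names, lam=0.0)
    return UnshrunkResult(P0=P0, method="analytic_limit",
                          diagnostics={"null_dimension": int(zero.sum())})


def _gcv_spline_extrapolate(
    x: np.ndarray, Z: np.ndarray, w: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted cubic smoothing splines for every column of ``Z`` at once.

    The smoothing penalty is selected per column by generalized
    cross-validation over a fixed log-spaced grid; the trace of the
    smoother matrix is obtained by co-fitting the identity columns. The
    value at 0 uses linear extrapolation from the boundary knot, the
    natural-spline convention. Returns (z at 0, weighted rms residual).
    """
    m, E = Z.shape
    augmented = np.hstack([Z, np.eye(m)])
    best_gcv = np.full(E, np.inf)
    best_z0 = np.full(E, np.nan)
    best_rss = np.full(E, np.inf)
    wsum = float(w.sum())
    for q in _PENALTY_GRID:
        spline = make_smoothing_spline(x, augmented, w=w, lam=float(q))
        fitted = spline(x)
        trace = float(np.trace(fitted[:, E:]))
        if trace >= m - 1e-9:
            continue                    # interpolating fit: GCV undefined
        value = spline(x[0])[:E]
        slope = spline.derivative()(x[0])[:E]
        z0 = value - x[0] * slope
        rss = (w[:, None] * (fitted[:, :E] - Z) ** 2).sum(axis=0)
        gcv = (rss / m) / (1.0 - trace / m) ** 2
        better = gcv < best_gcv
        best_gcv[better] = gcv[better]
        best_z0[better] = z0[better]
        best_rss[better] = rss[better]
    if np.isnan(best_z0).any():        # every penalty interpolated (tiny m)
        spline = make_smoothing_spline(x, Z, w=w, lam=float(_PENALTY_GRID[-1]))
        nan = np.isnan(best_z0)
        z0 = spline(x[0]) - x[0] * spline.derivative()(x[0])
        best_z0[nan] = np.atleast_1d(z0)[nan]
        best_rss[nan] = 0.0
    return best_z0, np.sqrt(best_rss / wsum)


def spline_unshrink(profile: LambdaProfile) -> UnshrunkResult:
    """Extrapolate the Fisher-transformed profile of every edge to 0."""
    if not np.isfinite(profile.z_values).all():
        raise ValueError("profile contains non-finite Fisher z values")
    z0, resid = _gcv_spline_extrapolate(
        profile.lambdas, profile.z_values, profile.weights
    )
    vals = np.tanh(z0)
    clamped = np.abs(vals) >= _CLAMP
    vals = np.clip(vals, -_CLAMP, _CLAMP)
    p = profile.p
    P = np.eye(p)
    iu = np.triu_indices(p, 1)
    P[iu] = vals
    P.T[iu] = vals
    P0 = PartialCorrelationMatrix(P, lam=0.0, variable_names=profile.variable_names)
    return UnshrunkResult(
        P0=P0,
        method="spline_extrapolation",
        diagnostics={
            "residual_rms": resid,
            "n_clamped": int(clamped.sum()),
            "grid": profile.lambdas,
        },
    )


def unshrunk_partial_correlation(
    data: DataMatrix,
    mode: str = "auto",
    grid: np.ndarray | None = None,
    analytic_cap: int = DEFAULT_ANALYTIC_CAP,
) -> UnshrunkResult:
    """Un-shrunk partial correlations of a dataset.

    ``mode='auto'`` takes the analytic limit for small problems
    (``p <= analytic_cap``) and falls back to the spline route when the
    problem is large or the analytic limit is degenerate.
    """
    if mode not in {"auto", "analytic", "spline"}:
        raise ValueError(f"unknown mode {mode!r}")
    model = sample_correlation(data)
    if mode == "analytic":
        return analytic_unshrunk_limit(model)
    if mode == "auto" and model.p <= analytic_cap:
        try:
            return analytic_unshrunk_limit(model)
        except np.linalg.LinAlgError:
            pass                        # degenerate limit: extrapolate instead
    lam_star = estimate_optimal_lambda(data)
    profile = lambda_profile(model, grid=grid, optimal_lambda=lam_star)
    return spline_unshrink(profile)
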