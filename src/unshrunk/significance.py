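"""Significance testing of (shrunk) partial correlations.

Under the null hypothesis of no conditional association, a shrunk partial
correlation rho computed at shrinkage lambda has density

    f0(rho) = ((1-lambda)^2 - rho^2)^((df-3)/2)
              / ( Beta(1/2, (df-1)/2) * (1-lambda)^(df-2) )

supported on (-(1-lambda), 1-lambda). At lambda = 0 this is the classical
null density of a partial correlation, whose degrees of freedom equal the
effective sample size (n minus the number of conditioned variables minus
one). The df parameter is fitted to the observed distribution of partial
correlations by maximum likelihood, and two-sided p-values follow from the
equivalent Beta law of (rho/(1-lambda))^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .shrinkage import PartialCorrelationMatrix

__all__ = [
    "NullModel",
    "EdgeTable",
    "null_density",
    "estimate_df_mle",
    "pcor_pvalue",
    "select_edges",
]

DF_LOWER = 3.0


@dataclass
class NullModel:
    """Fitted shrunk-null distribution of partial correlations."""

    lam: float
    df: float
    fit_loglik: float = float("nan")
    n_used: int = 0
    n_excluded: int = 0
    at_upper_bound: bool = False


def null_density(rho, lam: float, df: float):
    """Null density of the shrunk partial correlation; 0 outside support."""
    if df <= DF_LOWER:
        raise ValueError(f"df must exceed {DF_LOWER}, got {df}")
    if not 0.0 <= lam < 1.0:
        raise ValueError(f"lambda must be in [0, 1), got {lam}")
    rho = np.asarray(rho, dtype=float)
    width = 1.0 - lam
    inside = np.abs(rho) < width
    out = np.zeros_like(rho, dtype=float)
    log_norm = special.betaln(0.5, (df - 1.0) / 2.0) + (df - 2.0) * np.log(width)
    with np.errstate(invalid="ignore", divide="ignore"):
        logf = ((df - 3.0) / 2.0) * np.log(width**2 - rho**2) - log_norm
    out[inside] = np.exp(logf[inside]) if rho.ndim else float(np.exp(logf))
    return out if rho.ndim else float(out)


def _log_likelihood(df: float, rho: np.ndarray, lam: float) -> float:
    width = 1.0 - lam
    n = rho.size
    return float(
        ((df - 3.0) / 2.0) * np.log(width**2 - rho**2).sum()
        - n * (special.betaln(0.5, (df - 1.0) / 2.0) + (df - 2.0) * np.log(width))
    )


def estimate_df_mle(
    pcors, lam: float, df_max: float = 1e4
) -> NullModel:
    """Maximum-likelihood degrees of freedom of the shrunk null density.

    Values at or beyond the support edge |rho| >= 1 - lambda are excluded
    (their count is kept in the result). The likelihood is maximized by a
    bounded scalar search on (3, df_max]; hitting the upper bound is
    flagged, which happens for degenerate inputs such as all-zero pcors.
    """
    rho = np.asarray(pcors, dtype=float).ravel()
    width = 1.0 - lam
    keep = np.isfinite(rho) & (np.abs(rho) < width)
    n_excluded = int(rho.size - keep.sum())
    rho = rho[keep]
    if rho.size == 0:
        raise ValueError("no partial correlations inside the null support")
    if rho.size < 10:
        raise ValueError(f"need at least 10 usable pcors, got {rho.size}")
    res = optimize.minimize_scalar(
        lambda d: -_log_likelihood(d, rho, lam),
        bounds=(DF_LOWER + 1e-6, df_max),
        method="bounded",
        options={"xatol": 1e-6},
    )
    df = float(res.x)
    at_bound = df >= df_max * (1.0 - 1e-4)
    return NullModel(
        lam=lam,
        df=df,
        fit_loglik=float(-res.fun),
        n_used=int(rho.size),
        n_excluded=n_excluded,
        at_upper_bound=bool(at_bound),
    )


def pcor_pvalue(rho, null: NullModel):
    """Two-sided p-value P(|rho'| >= |rho|) under the shrunk null.

    Uses that (rho / (1-lambda))^2 follows a Beta(1/2, (df-1)/2) law, so
    the symmetric tail integral of the null density is the regularized
    incomplete beta survival function.
    """
    rho = np.asarray(rho, dtype=float)
    width = 1.0 - null.lam
    x = np.clip((rho / width) ** 2, 0.0, 1.0)
    p = stats.beta.sf(x, 0.5, (null.df - 1.0) / 2.0)
    p = np.where(np.abs(rho) >= width, 0.0, p)
    return p if rho.ndim else float(p)


@dataclass
class EdgeTable:
    """Per-pair records of partial correlation, p-value and selection flags."""

    frame: pd.DataFrame
    alpha: float
    magnitude_threshold: float

    @property
    def quadrant_counts(self) -> dict[str, int]:
        """Volcano-plot segmentation by |pcor| and significance thresholds."""
        mag = self.frame["passes_magnitude"]
        sig = self.frame["passes_significance"]
        return {
            "strong_significant": int((mag & sig).sum()),
            "strong_only": int((mag & ~sig).sum()),
            "significant_only": int((~mag & sig).sum()),
            "neither": int((~mag & ~sig).sum()),
        }

    @property
    def n_significant(self) -> int:
        return int(self.frame["passes_significance"].sum())

    def selected_nodes(self, require_magnitude: bool = False) -> list[str]:
        """Distinct nodes touched by significant (optionally strong) edges."""
        mask = self.frame["passes_significance"]
        if require_magnitude:
            mask = mask & self.frame["passes_magnitude"]
        sub = self.frame[mask]
        return sorted(set(sub["node_i"]) | set(sub["node_j"]))


def select_edges(
    P: PartialCorrelationMatrix,
    null: NullModel,
    alpha: float = 0.05,
    magnitude_threshold: float = 0.1,
) -> EdgeTable:
    """Score every unordered pair and flag magnitude/significance.

    Rows are ordered by |pcor| descending, ties broken by the
    lexicographic node pair.
    """
    if not 0.0 < alpha < 1.0 or not 0.0 < magnitude_threshold < 1.0:
        raise ValueError("alpha and magnitude_threshold must be in (0, 1)")
    iu = np.triu_indices(P.p, 1)
    pcor = P.values[iu]
    pval = pcor_pvalue(pcor, null)
    names = P.variable_names
    frame = pd.DataFrame(
        {
            "node_i": [names[i] for i in iu[0]],
            "node_j": [names[j] for j in iu[1]],
            "pcor": pcor,
            "pvalue": pval,
            "passes_magnitude": np.abs(pcor) >= magnitude_threshold,
            "passes_significance": pval < alpha,
        }
    )
    frame = frame.sort_values(
        by=["pcor", "node_i", "node_j"],
        key=lambda col: -col.abs() if col.name == "pcor" else col,
        ascending=True,
        kind="mergesort",
    ).reset_index(drop=True)
    return EdgeTable(frame=frame, alpha=alpha, magnitude_threshold=magnitude_threshold)
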