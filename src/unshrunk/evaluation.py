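"""Benchmark harness: edge-ranking AUROC, distance to the population
partial correlations, Bland-Altman comparability, and the full factorial
simulation study over sample sizes and replicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .shrinkage import (
    PartialCorrelationMatrix,
    estimate_optimal_lambda,
    sample_correlation,
    shrunk_partial_correlation,
)
from .simulate import GGMTruth, SimulationConfig, simulate_data, simulate_network
from .unshrink import lambda_profile, spline_unshrink

__all__ = [
    "BenchmarkResult",
    "auroc",
    "l1_to_truth",
    "bland_altman",
    "run_benchmark",
]


def auroc(scores, truth) -> float:
    """Rank-based area under the ROC curve (Mann-Whitney statistic)."""
    scores = np.asarray(scores, dtype=float).ravel()
    truth = np.asarray(truth, dtype=bool).ravel()
    if scores.shape != truth.shape:
        raise ValueError("scores and truth must have matching length")
    if truth.all() or not truth.any():
        raise ValueError("need at least one positive and one negative label")
    return float(roc_auc_score(truth, scores))


def l1_to_truth(
    P_hat: PartialCorrelationMatrix, truth: GGMTruth, edges: str = "all"
) -> float:
    """Mean absolute deviation from the population partial correlations.

    ``edges='all'`` averages over every unordered pair; ``edges='true'``
    restricts to the support of the generating network, which is where
    shrinkage bias (rather than null-edge noise) dominates.
    """
    if P_hat.p != truth.p:
        raise ValueError("dimension mismatch between estimate and truth")
    iu = np.triu_indices(truth.p, 1)
    dev = np.abs(P_hat.values - truth.pcor_true)[iu]
    if edges == "all":
        return float(dev.mean())
    if edges == "true":
        mask = truth.adjacency[iu]
        if not mask.any():
            raise ValueError("truth has no edges")
        return float(dev[mask].mean())
    raise ValueError(f"edges must be 'all' or 'true', got {edges!r}")


@dataclass
class BlandAltman:
    """Per-edge agreement summary between two estimates."""

    mean: np.ndarray
    difference: np.ndarray
    max_abs_difference: float


def bland_altman(
    P_a: PartialCorrelationMatrix, P_b: PartialCorrelationMatrix
) -> BlandAltman:
    """Difference-versus-average comparison of two pcor matrices."""
    if P_a.p != P_b.p:
        raise ValueError("dimension mismatch between the two estimates")
    a, b = P_a.offdiag(), P_b.offdiag()
    diff = a - b
    return BlandAltman(
        mean=(a + b) / 2.0,
        difference=diff,
        max_abs_difference=float(np.abs(diff).max()),
    )


@dataclass
class BenchmarkResult:
    """Tidy per-replicate benchmark table plus aggregation helpers."""

    table: pd.DataFrame                 # p, n, method, replicate, auroc, l1
    config: SimulationConfig

    def aggregate(self) -> pd.DataFrame:
        """Mean and sd of AUROC per (p, n, method), Tables-style layout."""
        g = self.table.groupby(["p", "n", "method"], as_index=False).agg(
            auroc_mean=("auroc", "mean"),
            auroc_sd=("auroc", "std"),
            l1_mean=("mean_l1_to_truth", "mean"),
        )
        return g.sort_values(["p", "n", "method"]).reset_index(drop=True)

    def paired_t_tests(self, method_a: str = "unshrunk", method_b: str = "shrunk") -> pd.DataFrame:
        """Two-sided paired t-test of per-replicate AUROCs at each n."""
        rows = []
        for n, sub in self.table.groupby("n"):
            a = sub[sub["method"] == method_a].sort_values("replicate")["auroc"].to_numpy()
            b = sub[sub["method"] == method_b].sort_values("replicate")["auroc"].to_numpy()
            if len(a) != len(b) or len(a) < 2:
                continue
            t, pval = stats.ttest_rel(a, b)
            rows.append({"n": n, "t": float(t), "pvalue": float(pval),
                         "mean_diff": float(np.mean(a - b))})
        return pd.DataFrame(rows)


def _estimate(method: str, data, model, lam_star, grid):
    if method == "shrunk":
        lam = max(lam_star, 1e-6)       # guard against exactly-zero shrinkage
        return shrunk_partial_correlation(model, lam)
    if method == "unshrunk":
        profile = lambda_profile(model, grid=grid, optimal_lambda=lam_star)
        return spline_unshrink(profile).P0
    raise ValueError(f"unknown method {method!r}")


def run_benchmark(
    config: SimulationConfig, methods: tuple[str, ...] = ("unshrunk", "shrunk")
) -> BenchmarkResult:
    """Full factorial: every (n, replicate) with one fresh network each.

    Replicate r uses ``config.seed + r`` for the network and data, so the
    same simulated datasets are scored by every method (paired design).
    Edges are ranked by |pcor|.
    """
    iu = np.triu_indices(config.p, 1)
    rows = []
    for r in range(config.n_replicates):
        truth = simulate_network(
            config.p, config.frac_nonzero, seed=config.seed + r,
            effect_range=config.effect_range,
        )
        labels = truth.adjacency[iu]
        for n in config.n_values:
            data = simulate_data(truth, n, seed=config.seed + 10_000 * (r + 1) + n)
            model = sample_correlation(data)
            lam_star = estimate_optimal_lambda(data)
            for method in methods:
                P = _estimate(method, data, model, lam_star, config.lambda_grid)
                rows.append(
                    {
                        "p": config.p,
                        "n": n,
                        "method": method,
                        "replicate": r,
                        "auroc": auroc(np.abs(P.values[iu]), labels),
                        "mean_l1_to_truth": l1_to_truth(P, truth),
                        "lambda_star": lam_star,
                    }
                )
    return BenchmarkResult(table=pd.DataFrame(rows), config=config)
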