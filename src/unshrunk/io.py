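"""File ingestion and serialization: expression matrices, edge tables,
network files and machine-readable run reports."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datamatrix import DataMatrix
from .significance import EdgeTable
from .simulate import GGMTruth

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "write_edge_table",
    "write_run_report",
    "write_truth",
]

ORIENTATIONS = ("samples_by_variables", "variables_by_samples")


def _separator(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression_matrix(path: str | Path, orientation: str) -> DataMatrix:
    """Read a TSV/CSV expression matrix into samples x variables form.

    Orientation is explicit; files are never sniffed. The first column is
    used as row labels when it is non-numeric.
    """
    if orientation not in ORIENTATIONS:
        raise ValueError(f"orientation must be one of {ORIENTATIONS}, got {orientation!r}")
    path = Path(path)
    sep = _separator(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    seen: set[str] = set()
    for name in header:
        if name and name in seen:
            raise ValueError(f"duplicate variable name: {name!r}")
        seen.add(name)
    frame = pd.read_csv(path, sep=sep)
    first = frame.columns[0]
    if frame[first].dtype == object:
        frame = frame.set_index(first)
    if orientation == "variables_by_samples":
        frame = frame.T
    try:
        values = frame.to_numpy(dtype=float)
    except (TypeError, ValueError) as err:
        raise ValueError(f"non-numeric cell in {path.name}: {err}") from err
    names = [str(c) for c in frame.columns]
    return DataMatrix(values, names)


def write_expression_matrix(data: DataMatrix, path: str | Path) -> None:
    path = Path(path)
    data.to_dataframe().to_csv(path, sep=_separator(path), index=False)


def write_edge_table(table: EdgeTable, path: str | Path, format: str = "tsv") -> None:
    """Serialize an edge table as TSV (all pairs) or SIF (selected only)."""
    path = Path(path)
    if format == "tsv":
        out = table.frame.copy()
        out["pcor"] = out["pcor"].map("{:.10g}".format)
        out["pvalue"] = out["pvalue"].map("{:.10g}".format)
        out.to_csv(path, sep="\t", index=False)
    elif format == "sif":
        selected = table.frame[table.frame["passes_significance"]]
        lines = [f"{r.node_i} pc {r.node_j}" for r in selected.itertuples()]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    else:
        raise ValueError(f"format must be 'tsv' or 'sif', got {format!r}")


def write_run_report(report: dict, path: str | Path) -> None:
    """JSON report with everything needed to reproduce a run."""

    def _default(obj):
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        raise TypeError(f"not JSON serializable: {type(obj)}")

    Path(path).write_text(json.dumps(report, indent=2, default=_default) + "\n")


def write_truth(truth: GGMTruth, path: str | Path) -> None:
    """Ground-truth network as JSON: edge list plus dense precision."""
    iu = np.triu_indices(truth.p, 1)
    mask = truth.adjacency[iu]
    edges = [
        {"i": int(i), "j": int(j), "pcor": float(truth.pcor_true[i, j])}
        for i, j in zip(iu[0][mask], iu[1][mask])
    ]
    payload = {
        "p": truth.p,
        "frac_nonzero": truth.frac_nonzero,
        "seed": truth.seed,
        "edges": edges,
        "precision": truth.precision.tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
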