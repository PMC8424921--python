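"""Samples-by-variables data container used throughout the package.

Expression matrices arrive either as samples x variables or transposed;
:class:`DataMatrix` always stores samples in rows. Columns may be
standardized (mean 0, unit sample standard deviation), which is the default
preprocessing before any correlation-model fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["DataMatrix"]


@dataclass
class DataMatrix:
    """A complete numeric matrix of ``n`` samples by ``p`` variables.

    Parameters
    ----------
    values
        Real matrix of shape ``(n, p)`` with no missing entries.
    variable_names
        ``p`` unique identifiers, one per column. Auto-generated
        (``V1 .. Vp``) when omitted.
    standardized
        True when each column has mean 0 and unit sample standard
        deviation (ddof=1).
    """

    values: np.ndarray
    variable_names: list[str] = field(default_factory=list)
    standardized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D samples x variables matrix")
        n, p = self.values.shape
        if n < 2:
            raise ValueError(f"need at least 2 samples, got {n}")
        if p < 2:
            raise ValueError(f"need at least 2 variables, got {p}")
        if not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))
            raise ValueError(
                f"missing/non-finite value at sample {bad[0][0]}, column {bad[0][1]}"
            )
        if not self.variable_names:
            self.variable_names = [f"V{j + 1}" for j in range(p)]
        if len(self.variable_names) != p:
            raise ValueError(
                f"{len(self.variable_names)} variable names for {p} columns"
            )
        dup = pd.Index(self.variable_names).duplicated()
        if dup.any():
            name = self.variable_names[int(np.flatnonzero(dup)[0])]
            raise ValueError(f"duplicate variable name: {name!r}")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, standardized: bool = False) -> "DataMatrix":
        return cls(frame.to_numpy(dtype=float), list(map(str, frame.columns)), standardized)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.variable_names)

    def standardize(self) -> "DataMatrix":
        """Return a copy with columns centred and scaled to unit sd (ddof=1).

        Raises on zero-variance columns, naming the first offender.
        """
        if self.standardized:
            return self
        sd = self.values.std(axis=0, ddof=1)
        zero = sd <= 0
        if zero.any():
            name = self.variable_names[int(np.flatnonzero(zero)[0])]
            raise ValueError(f"zero-variance column: {name!r}")
        centred = self.values - self.values.mean(axis=0)
        return DataMatrix(centred / sd, list(self.variable_names), standardized=True)
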