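"""Small closed-form matrices used in examples and tests.

``PITFALL_COVARIANCE`` is a 4x4 covariance whose two strongest partial
correlations swap order as the shrinkage intensity grows — the textbook
illustration that shrinkage biases partial correlations non-linearly.
``all_ones_correlation`` is the maximally correlated (singular) case whose
un-shrunk partial correlations have the exact limit 1/(p-1).
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np

__all__ = ["PITFALL_COVARIANCE", "pitfall_precision", "all_ones_correlation"]

#: 4x4 unit-diagonal covariance with a unique shrinkage order reversal
PITFALL_COVARIANCE = np.array(
    [
        [1.0, 1 / 2, -1 / 4, -1 / 8],
        [1 / 2, 1.0, -3 / 4, -3 / 4],
        [-1 / 4, -3 / 4, 1.0, 3 / 4],
        [-1 / 8, -3 / 4, 3 / 4, 1.0],
    ]
)


def pitfall_precision() -> np.ndarray:
    """Exact inverse of :data:`PITFALL_COVARIANCE` (entries k/97)."""
    num = np.array(
        [
            [160, -152, -8, -88],
            [-152, 416, 124, 200],
            [-8, 124, 272, -112],
            [-88, 200, -112, 320],
        ]
    )
    return num / 97.0


def pitfall_precision_fractions() -> list[list[Fraction]]:
    """The same inverse in exact rational arithmetic (oracle use)."""
    num = pitfall_precision() * 97.0
    return [[Fraction(int(round(v)), 97) for v in row] for row in num]


def all_ones_correlation(p: int = 3) -> np.ndarray:
    """The rank-one p x p correlation matrix of all ones."""
    if p < 2:
        raise ValueError("need p >= 2")
    return np.ones((p, p))
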