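"""Winsorized and Pearson correlation kernels.

The gamma-Winsorized correlation clamps each variable independently at its
extreme order statistics — with g = floor(gamma * n), the g smallest values
are replaced by the (g+1)-th order statistic and the g largest by the
(n-g)-th — and then applies the plain Pearson formula to the two clamped
vectors.  gamma = 0.1 is the study default; gamma = 0 reduces exactly to
Pearson.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, ParameterError


@dataclass(frozen=True)
class WincorrParams:
    """Winsorization proportion per tail; must satisfy 0 <= gamma < 0.5."""

    gamma: float = 0.1

    def __post_init__(self) -> None:
        _check_gamma(self.gamma)


def _check_gamma(gamma: float) -> None:
    if not 0 <= gamma < 0.5:
        raise ParameterError(f"gamma must be in [0, 0.5), got {gamma}")


def winsorize(x, gamma: float) -> np.ndarray:
    """Clamp both tails at the g-th order statistics, preserving order."""
    _check_gamma(gamma)
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2:
        raise DegenerateInputError("winsorize needs n >= 2")
    g = math.floor(gamma * n)
    if g == 0:
        return x.copy()
    xs = np.sort(x)
    return np.clip(x, xs[g], xs[n - g - 1])


def pearson(x, y) -> float:
    """Product-moment correlation with an explicit degenerate-input guard."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise DegenerateInputError("correlation needs n >= 3")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = float(xc @ xc)
    sy = float(yc @ yc)
    if sx == 0.0 or sy == 0.0:
        raise DegenerateInputError("zero variance in correlation input")
    return float(np.clip((xc @ yc) / math.sqrt(sx * sy), -1.0, 1.0))


def wincorr(x, y, gamma: float = 0.1) -> float:
    """Pearson correlation of the two independently winsorized vectors."""
    return pearson(winsorize(x, gamma), winsorize(y, gamma))
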