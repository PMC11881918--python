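"""Directed (projected) motion from cumulative x/y displacement.

Tissue within one ROI contracts along a fairly fixed axis.  An ordinary
least-squares fit of the cumulative y-shift on the cumulative x-shift
gives a slope ``a``; the unit direction vector is then

    L = sqrt(a^2 + 1),  (X, Y) = (1/L, a/L),

and the projected trace ``x*X + y*Y`` collapses the 2-D motion onto that
axis, yielding a signed 1-D trace of directed displacement per frame.
A vertical contraction axis (constant x, varying y) cannot be represented
by a finite slope; in that case the fit is performed with the axes
swapped and the unit vector constructed accordingly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import Trace

__all__ = [
    "DirectionVector",
    "direction_slope",
    "direction_vector",
    "fit_direction",
    "projected_velocity",
]


@dataclass(frozen=True)
class DirectionVector:
    """Unit direction (X, Y) derived from regression slope a; L = sqrt(a^2+1)."""

    X: float
    Y: float
    a: float = math.nan       # slope of y on x; nan when the axis is vertical
    L: float = math.nan       # sqrt(a^2 + 1); nan when the axis is vertical

    def __post_init__(self) -> None:
        if not math.isclose(self.X ** 2 + self.Y ** 2, 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValueError("direction vector must have unit length")


def direction_slope(x: Trace, y: Trace) -> float:
    """OLS slope of y on x.  Raises for constant x (vertical axis)."""
    xv, yv = np.asarray(x.values), np.asarray(y.values)
    if len(xv) != len(yv) or len(xv) < 2:
        raise ValueError("x and y traces must have equal length >= 2")
    xc = xv - xv.mean()
    sxx = float(xc @ xc)
    if sxx < 1e-24:
        raise ValueError(
            "x displacement is constant: the motion axis is vertical; "
            "use fit_direction, which handles this case by swapping axes")
    return float(xc @ (yv - yv.mean()) / sxx)


def direction_vector(a: float) -> DirectionVector:
    """Unit vector (1/L, a/L) with L = sqrt(a^2 + 1)."""
    if not math.isfinite(a):
        raise ValueError("slope must be finite")
    L = math.sqrt(a * a + 1.0)
    return DirectionVector(X=1.0 / L, Y=a / L, a=a, L=L)


def fit_direction(x: Trace, y: Trace) -> DirectionVector:
    """Fit the contraction axis from cumulative coordinates.

    Falls back to regressing x on y when x is (numerically) constant, so a
    purely vertical motion axis is still representable as a unit vector.
    """
    try:
        return direction_vector(direction_slope(x, y))
    except ValueError:
        yv = np.asarray(y.values)
        yc = yv - yv.mean()
        syy = float(yc @ yc)
        if syy < 1e-24:
            raise ValueError("both coordinates constant: no motion to fit")
        b = float(yc @ (np.asarray(x.values) - np.asarray(x.values).mean()) / syy)
        L = math.sqrt(b * b + 1.0)
        return DirectionVector(X=b / L, Y=1.0 / L)


def projected_velocity(x: Trace, y: Trace, d: DirectionVector) -> Trace:
    """Pointwise projection x*X + y*Y of the displacement onto the axis.

    The result is the signed directed displacement per frame; event-level
    "maximum velocity" is later taken as the largest absolute first
    difference of this trace divided by dt.
    """
    if len(x) != len(y):
        raise ValueError("x and y traces must have equal length")
    return x.with_values(x.values * d.X + y.values * d.Y, name="projected")
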