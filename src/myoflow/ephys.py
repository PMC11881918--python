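"""Voltage-ramp quantitation and Hill dose-response fitting.

Whole-cell currents are elicited by voltage ramps (typically -80 to
+80 mV from a holding potential of 0 mV).  The scalar read-outs are the
current interpolated at -80 mV, the current density (current divided by
membrane capacitance, a proxy for cell surface area), and the fold
increase FI = |I_treated| / |I_control| at a fixed voltage.

Concentration-response data are fitted with a Hill model with the
baseline fixed at FI = 1 (control is its own normalizer):

    activation:  FI(c) = 1 + (plateau - 1) c^h / (c^h + EC50^h)
    inhibition:  FI(c) = top - (top - 1) c^h / (c^h + IC50^h)

by nonlinear least squares with multiple log-spaced EC50/IC50 starts;
the best-residual solution wins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .synthetic import DoseResponsePoint, hill_activation, hill_inhibition

__all__ = [
    "RampRecording",
    "HillFit",
    "current_at",
    "current_density",
    "fold_increase",
    "fit_hill_activation",
    "fit_hill_inhibition",
]

logger = logging.getLogger(__name__)

HILL_BOUNDS = (0.2, 6.0)          # biologically plausible Hill slopes
NO_RESPONSE_SPAN = 0.05           # plateau within this of baseline => flat
POOR_FIT_R2 = 0.5


@dataclass
class RampRecording:
    """One voltage-ramp sweep: voltage (mV), current (pA), capacitance (pF)."""

    voltage: np.ndarray
    current: np.ndarray
    capacitance: float
    label: str = ""

    def __post_init__(self) -> None:
        self.voltage = np.asarray(self.voltage, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        if self.voltage.shape != self.current.shape or self.voltage.ndim != 1:
            raise ValueError("voltage and current must be 1-D of equal length")
        dv = np.diff(self.voltage)
        if not ((dv > 0).all() or (dv < 0).all()):
            raise ValueError("voltage must be strictly monotone over the ramp")
        if self.capacitance <= 0:
            raise ValueError("capacitance must be positive")


@dataclass
class HillFit:
    """Fitted dose-response parameters."""

    half_max: float           # EC50 or IC50, uM
    hill_coefficient: float
    plateau: float            # top fold for activation, starting fold for inhibition
    baseline: float           # fixed at 1 (control-normalized)
    residual: float           # sum of squared residuals
    r_squared: float
    mode: str                 # "activation" | "inhibition"
    no_response: bool = False
    poor_fit: bool = False


def current_at(recording: RampRecording, voltage: float = -80.0) -> float:
    """Linear interpolation of the ramp current at the requested voltage."""
    v, i = recording.voltage, recording.current
    lo, hi = min(v[0], v[-1]), max(v[0], v[-1])
    if not (lo <= voltage <= hi):
        raise ValueError(f"voltage {voltage} mV outside ramp span [{lo}, {hi}]")
    if v[0] > v[-1]:
        v, i = v[::-1], i[::-1]
    return float(np.interp(voltage, v, i))


def current_density(current: float, capacitance: float) -> float:
    """Capacitance-normalized current, pA/pF."""
    if capacitance <= 0:
        raise ValueError("capacitance must be positive")
    return current / capacitance


def fold_increase(treated: float, control: float,
                  noise_floor: float = 1e-9) -> float:
    """|treated| / |control| at a common voltage; scale-invariant, >= 0."""
    if abs(control) <= noise_floor:
        raise ValueError(
            "control current is at the noise floor; report current density "
            "instead of a fold increase")
    return abs(treated) / abs(control)


def _fit_hill(points: Sequence[DoseResponsePoint], mode: str) -> HillFit:
    conc = np.array([p.concentration for p in points], dtype=float)
    fi = np.array([p.fold_increase for p in points], dtype=float)
    if len(np.unique(conc)) < 4:
        raise ValueError("need at least 4 distinct concentrations")

    model = hill_activation if mode == "activation" else hill_inhibition
    pos = conc[conc > 0]
    k_starts = np.geomspace(pos.min() / 3.0, pos.max() * 3.0, 7)
    plateau0 = max(fi.max(), 1.0 + 1e-6)
    lower = [pos.min() / 1e3, HILL_BOUNDS[0], 1.0]
    upper = [pos.max() * 1e3, HILL_BOUNDS[1], max(10.0 * plateau0, 10.0)]

    best = None
    for k0 in k_starts:
        p0 = [k0, 1.0, plateau0]
        try:
            popt, _ = curve_fit(model, conc, fi, p0=p0,
                                bounds=(lower, upper), maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((model(conc, *popt) - fi) ** 2))
        if best is None or rss < best[1]:
            best = (popt, rss)
    if best is None:
        raise RuntimeError("Hill fit failed to converge from every start")

    (half, h, plateau), rss = best
    tss = float(np.sum((fi - fi.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    no_response = bool(abs(plateau - 1.0) < NO_RESPONSE_SPAN)
    poor = bool((not no_response) and r2 < POOR_FIT_R2)
    if no_response:
        logger.warning("Hill fit (%s): plateau ~ baseline, no response", mode)
    if poor:
        logger.warning("Hill fit (%s): poor fit, r^2 = %.2f", mode, r2)
    return HillFit(half_max=float(half), hill_coefficient=float(h),
                   plateau=float(plateau), baseline=1.0, residual=rss,
                   r_squared=r2, mode=mode, no_response=no_response,
                   poor_fit=poor)


def fit_hill_activation(points: Sequence[DoseResponsePoint]) -> HillFit:
    """Fit the ascending Hill model; returns EC50, slope, plateau, residual."""
    return _fit_hill(points, "activation")


def fit_hill_inhibition(points: Sequence[DoseResponsePoint]) -> HillFit:
    """Fit the descending Hill model; returns IC50, slope, top, residual.

    Ascending data fed to this routine produce a flat or poor fit, which
    is flagged on the returned object.
    """
    return _fit_hill(points, "inhibition")
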