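"""Classical forced-oscillation (FOT) indexes from an averaged impedance spectrum.

Eleven indexes are derived per exam:

* resistive — R0 and S, intercept and slope of the ordinary least-squares
  line fitted to resistance over 4-16 Hz; Rm, the mean resistance over the
  same band; R4 and R20, resistance at 4 and 20 Hz; and their difference
  R4-R20 (small-airway obstruction / ventilation inhomogeneity);
* reactive — Xm, mean reactance over 4-32 Hz; Fr, the resonant frequency
  where reactance crosses zero; Cdyn = -1/(2*pi*4*X4), the dynamic
  compliance from the 4 Hz reactance; Ax, the area enclosed by the negative
  reactance curve between 4 Hz and Fr; and Z4 = sqrt(R4^2 + X4^2), the
  impedance modulus at 4 Hz.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np

from .eric_model import ImpedanceSpectrum

__all__ = ["FOTFeatures", "FOT_FEATURE_NAMES", "resistance_line", "reactance_features",
           "point_resistances", "extract_fot_features"]

#: Canonical order of the 11 FOT indexes.
FOT_FEATURE_NAMES = ["R0", "S", "Rm", "R4", "R20", "R4_R20", "Xm", "Fr", "Cdyn", "Ax", "Z4"]

#: Fr values are capped here when linear extrapolation beyond the measured
#: band is needed (no zero crossing below 32 Hz).
FR_CAP_HZ = 64.0


@dataclass(frozen=True)
class FOTFeatures:
    """The 11 FOT indexes of one exam.

    ``Cdyn`` is NaN when the 4 Hz reactance is non-negative (the defining
    inversion would give a non-positive compliance).
    """

    R0: float
    S: float
    Rm: float
    R4: float
    R20: float
    R4_R20: float
    Xm: float
    Fr: float
    Cdyn: float
    Ax: float
    Z4: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _band(spectrum: ImpedanceSpectrum, lo: float, hi: float) -> np.ndarray:
    f = spectrum.frequencies
    return (f >= lo - 1e-9) & (f <= hi + 1e-9)


def resistance_line(spectrum: ImpedanceSpectrum) -> tuple[float, float, float]:
    """OLS intercept R0, slope S and mean Rm of resistance over 4-16 Hz.

    Boundaries inclusive; requires at least two in-band points.
    """
    mask = _band(spectrum, 4.0, 16.0)
    if mask.sum() < 2:
        raise ValueError(
            f"resistance regression needs >= 2 points in 4-16 Hz, got {int(mask.sum())}"
        )
    f = spectrum.frequencies[mask]
    r = spectrum.resistance[mask]
    slope, intercept = np.polyfit(f, r, 1)
    return float(intercept), float(slope), float(r.mean())


def point_resistances(spectrum: ImpedanceSpectrum) -> tuple[float, float, float]:
    """Resistance at 4 and 20 Hz (exact grid lookups) and their difference."""
    try:
        r4 = spectrum.at(4.0).real
    except ValueError:
        raise ValueError("spectrum has no 4 Hz point (required for R4)") from None
    try:
        r20 = spectrum.at(20.0).real
    except ValueError:
        raise ValueError("spectrum has no 20 Hz point (required for R20)") from None
    return float(r4), float(r20), float(r4 - r20)


def _interpolated_crossing(f: np.ndarray, x: np.ndarray) -> float:
    """Resonant frequency by linear interpolation of the first zero crossing.

    If the reactance stays negative up to the last grid point, the crossing
    is linearly extrapolated from the last two points and capped at
    ``FR_CAP_HZ``.  If the reactance is non-negative already at the first
    point, the band start is returned.
    """
    if x[0] >= 0:
        return float(f[0])
    neg = x < 0
    if neg.all():
        f1, f2 = f[-2], f[-1]
        x1, x2 = x[-2], x[-1]
        if x2 <= x1:  # not heading toward zero; cap
            return FR_CAP_HZ
        fr = f2 + (0.0 - x2) * (f2 - f1) / (x2 - x1)
        return float(min(fr, FR_CAP_HZ))
    i = int(np.argmax(~neg))  # first non-negative index; i >= 1 here
    f1, f2 = f[i - 1], f[i]
    x1, x2 = x[i - 1], x[i]
    if x2 == x1:
        return float(f1)
    return float(f1 + (0.0 - x1) * (f2 - f1) / (x2 - x1))


def reactance_features(spectrum: ImpedanceSpectrum) -> tuple[float, float, float, float, float]:
    """Reactive indexes (Xm, Fr, Cdyn, Ax, Z4) of a spectrum.

    Xm is the grid mean of reactance over 4-32 Hz.  Fr interpolates the zero
    crossing linearly between bracketing grid points (extrapolated from the
    last two points, capped at 64 Hz, when no crossing is measured).  Ax is
    the trapezoidal integral of max(0, -X) from 4 Hz to min(Fr, 32 Hz) on
    the measured grid augmented with the interpolated crossing point.
    Cdyn = -1/(2*pi*4*X4) and is NaN when X4 >= 0.  Z4 is the impedance
    modulus at 4 Hz.
    """
    mask = _band(spectrum, 4.0, 32.0)
    f = spectrum.frequencies[mask]
    x = spectrum.reactance[mask]
    if f.size == 0 or not math.isclose(f[0], 4.0, abs_tol=1e-9):
        raise ValueError("spectrum has no 4 Hz point (required for X4)")
    x4 = float(x[0])
    r4 = float(spectrum.resistance[mask][0])

    xm = float(x.mean())
    fr = _interpolated_crossing(f, x)
    cdyn = float("nan") if x4 >= 0 else float(-1.0 / (2.0 * np.pi * 4.0 * x4))
    z4 = float(np.hypot(r4, x4))

    # Area of the negative reactance lobe, observed band only.
    stop = min(fr, float(f[-1]))
    if stop <= f[0] or x4 >= 0:
        ax = 0.0
    else:
        grid = f[f < stop]
        vals = x[f < stop]
        if stop > grid[-1]:
            # append the crossing (or the 32 Hz boundary value) as endpoint
            x_stop = 0.0 if fr <= f[-1] else float(np.interp(stop, f, x))
            grid = np.append(grid, stop)
            vals = np.append(vals, x_stop)
        ax = float(np.trapezoid(np.maximum(0.0, -vals), grid))
    return xm, fr, cdyn, ax, z4


def extract_fot_features(spectrum: ImpedanceSpectrum) -> FOTFeatures:
    """All 11 FOT indexes of one averaged spectrum."""
    r0, s, rm = resistance_line(spectrum)
    r4, r20, diff = point_resistances(spectrum)
    xm, fr, cdyn, ax, z4 = reactance_features(spectrum)
    return FOTFeatures(R0=r0, S=s, Rm=rm, R4=r4, R20=r20, R4_R20=diff,
                       Xm=xm, Fr=fr, Cdyn=cdyn, Ax=ax, Z4=z4)
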