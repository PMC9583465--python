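"""Inverse eRIC problem: estimate (R, Rp, I, C) from a measured spectrum.

The estimator minimises the stacked squared residuals of the real and
imaginary parts of the eRIC model against the measured resistance and
reactance, using a bounded trust-region damped least-squares solver (the
bounded counterpart of Levenberg-Marquardt).  The loss surface has mirror
local minima in the (Rp, C) split, so a fixed multi-start list derived from
data landmarks (low/high-frequency resistance, reactance slope, resonant
frequency) is tried and the best residual kept.  The procedure is fully
deterministic for a given spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .eric_model import ERICParameters, ImpedanceSpectrum, eric_impedance
from .fot_features import FOTFeatures, FOT_FEATURE_NAMES

__all__ = ["FitResult", "fit_eric", "assemble_features", "FEATURE_COLUMNS",
           "write_features", "read_features"]

#: Fixed column order of the combined 16-feature table: 11 FOT indexes then
#: the five eRIC components.
FEATURE_COLUMNS = FOT_FEATURE_NAMES + ["R", "Rp", "I", "C", "Rt"]

_C_FLOOR = 1e-6  # compliance lower bound (L/cmH2O); keeps the model defined


@dataclass(frozen=True)
class FitResult:
    """Outcome of one eRIC parameter estimation."""

    params: ERICParameters
    residual: float
    converged: bool
    iterations: int
    start: ERICParameters

    def __post_init__(self) -> None:
        if self.residual < 0:
            raise ValueError("residual sum of squares cannot be negative")


def _residuals(theta: np.ndarray, f: np.ndarray, re: np.ndarray, im: np.ndarray) -> np.ndarray:
    R, Rp, I, C = theta
    w = 2.0 * np.pi * f
    denom = 1.0 + (w * Rp * C) ** 2
    model_re = R + Rp / denom
    model_im = w * I - w * Rp**2 * C / denom
    return np.concatenate([model_re - re, model_im - im])


def _start_points(spectrum: ImpedanceSpectrum) -> list[ERICParameters]:
    """Data-driven multi-start list.

    Landmarks: the low-frequency resistance approximates R + Rp, the
    high-frequency resistance approximates R, and the high-frequency
    reactance slope approximates 2*pi*I.  C is scanned over a decade grid
    because the (Rp, C) split is the bistable direction of the loss surface.
    """
    f = spectrum.frequencies
    re = spectrum.resistance
    im = spectrum.reactance
    r_lo = max(float(re[0]), 1e-3)
    r_hi = max(float(re[-1]), 1e-3)
    rt = max(r_lo, r_hi)
    # inertance from the high-frequency reactance slope X ~ 2*pi*f*I
    if len(f) >= 2:
        i_est = (im[-1] - im[-2]) / (2.0 * np.pi * (f[-1] - f[-2]))
    else:
        i_est = 0.01
    i_candidates = sorted({max(float(i_est), 1e-4), 0.005, 0.02})
    starts: list[ERICParameters] = []
    for frac in (0.25, 0.5, 0.75):
        R0 = max(r_hi * (1 - frac) + 1e-3, 1e-3)
        Rp0 = max(rt - R0, 0.1)
        for c0 in (0.005, 0.02, 0.08):
            for i0 in i_candidates:
                starts.append(ERICParameters(R=R0, Rp=Rp0, I=i0, C=c0))
    return starts


def fit_eric(spectrum: ImpedanceSpectrum, starts: list[ERICParameters] | None = None) -> FitResult:
    """Estimate eRIC parameters from a spectrum by bounded damped least squares.

    Parameters
    ----------
    spectrum : ImpedanceSpectrum
        Measured (or simulated) spectrum with at least four frequency points.
    starts : list of ERICParameters, optional
        Override the default multi-start list.

    Returns
    -------
    FitResult
        Best-residual solution across all starts.  ``converged`` is False
        when no start converged; no exception is raised in that case.
    """
    if len(spectrum.frequencies) < 4:
        raise ValueError(
            f"need >= 4 frequency points to fit 4 parameters, got {len(spectrum.frequencies)}"
        )
    f = spectrum.frequencies
    re = spectrum.resistance
    im = spectrum.reactance
    starts = starts if starts is not None else _start_points(spectrum)

    best: FitResult | None = None
    lower = np.array([0.0, 0.0, 0.0, _C_FLOOR])
    upper = np.full(4, np.inf)
    for s in starts:
        x0 = np.clip(s.as_array(), lower, None)
        try:
            sol = least_squares(
                _residuals, x0, bounds=(lower, upper), args=(f, re, im),
                method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=2000,
            )
        except Exception:
            continue
        res = float(np.sum(sol.fun**2))
        cand = FitResult(
            params=ERICParameters(*[float(v) for v in sol.x]),
            residual=res,
            converged=bool(sol.success),
            iterations=int(sol.nfev),
            start=s,
        )
        if best is None or (cand.converged and not best.converged) or (
            cand.converged == best.converged and res < best.residual
        ):
            best = cand
    if best is None:  # every start raised
        fallback = starts[0]
        best = FitResult(
            params=fallback,
            residual=float(np.sum(_residuals(fallback.as_array(), f, re, im) ** 2)),
            converged=False,
            iterations=0,
            start=fallback,
        )
    return best


def assemble_features(fot: FOTFeatures, fit: FitResult) -> dict[str, float]:
    """Combine the 11 FOT indexes and the five eRIC components.

    Returns a dict in the fixed :data:`FEATURE_COLUMNS` order, plus a
    ``fit_converged`` flag downstream consumers may use to impute or drop.
    """
    rec = fot.as_dict()
    rec.update(
        R=fit.params.R, Rp=fit.params.Rp, I=fit.params.I, C=fit.params.C, Rt=fit.params.Rt
    )
    rec = {name: float(rec[name]) for name in FEATURE_COLUMNS}
    rec["fit_converged"] = bool(fit.converged)
    return rec


def write_features(table: pd.DataFrame, path) -> None:
    """Write a feature table so that reading it back is bit-identical."""
    table.to_csv(path, float_format="%.17g")


def read_features(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="subject_id", float_precision="round_trip")


def features_table(records, fits=None, converged_policy: str = "drop") -> pd.DataFrame:
    """16-feature table for a cohort of subject records.

    Parameters
    ----------
    records : list of SubjectRecord
    fits : list of FitResult, optional
        Precomputed fits aligned with ``records``; computed here otherwise.
    converged_policy : {"drop", "keep"}
        What to do with subjects whose eRIC fit did not converge.

    Returns
    -------
    pandas.DataFrame
        Indexed by subject_id with columns ``FEATURE_COLUMNS`` + ``group``.
    """
    from .fot_features import extract_fot_features

    if converged_policy not in ("drop", "keep"):
        raise ValueError(f"unknown converged_policy {converged_policy!r}")
    rows = {}
    groups = {}
    for i, rec in enumerate(records):
        fit = fits[i] if fits is not None else fit_eric(rec.spectrum)
        row = assemble_features(extract_fot_features(rec.spectrum), fit)
        if not row.pop("fit_converged") and converged_policy == "drop":
            continue
        rows[rec.subject_id] = row
        groups[rec.subject_id] = rec.group
    table = pd.DataFrame.from_dict(rows, orient="index")[FEATURE_COLUMNS]
    table.index.name = "subject_id"
    table["group"] = pd.Series(groups)
    return table
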