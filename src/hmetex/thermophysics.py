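"""Specific heat capacity from scanning microcalorimetry.

A continuous cp scan records the differential heat flow into a hydrated
protein sample while the cell temperature is ramped at a slow, constant
rate beta.  The apparent heat capacity follows from

    cp(T) = (phi_sample(T) - phi_blank(T)) / (m * beta),

with beta converted to K/s so that cp comes out in J kg^-1 K^-1.  The
instrument is calibrated against distilled water: a temperature-wise
correction factor k(T) = cp_water,lit(T) / cp_water,measured(T) is applied
multiplicatively to every sample point.

Two regression models summarize the corrected data: a per-moisture linear
model cp = c0 + c1*T, and a multiple linear regression over water mass
fraction and temperature, cp = y0 + a*Xw + b*T, valid (for the proteins
studied here) on Xw in [0.6, 0.7] and T in [40, 115] degC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import statsmodels.api as sm

__all__ = [
    "CpScan",
    "CpPoint",
    "CpLinearModel",
    "CpMlrModel",
    "ExtrapolationWarning",
    "water_cp_literature",
    "cp_from_heatflow",
    "fit_cp_linear",
    "fit_cp_mlr",
    "predict_cp",
    "water_extrapolation_error",
]


class ExtrapolationWarning(UserWarning):
    """Prediction requested outside a model's fitted validity box."""


# Saturated liquid water heat capacity, J kg^-1 K^-1, standard steam-table
# values on 0-150 degC; linear interpolation between nodes.
_WATER_CP_T = np.array(
    [0.0, 10.0, 20.0, 25.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0,
     90.0, 100.0, 110.0, 120.0, 130.0, 140.0, 150.0]
)
_WATER_CP = np.array(
    [4219.9, 4195.5, 4184.4, 4181.6, 4180.1, 4179.6, 4181.7, 4185.1,
     4190.1, 4196.9, 4205.4, 4215.7, 4228.8, 4244.5, 4263.1, 4285.1, 4310.5]
)


def water_cp_literature(temperature_C):
    """Reference cp of liquid water in J kg^-1 K^-1 on 0-150 degC."""
    t = np.asarray(temperature_C, dtype=float)
    if np.any(t < _WATER_CP_T[0]) or np.any(t > _WATER_CP_T[-1]):
        raise ValueError("water cp reference defined on 0-150 degC only")
    out = np.interp(t, _WATER_CP_T, _WATER_CP)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class CpScan:
    """One calorimetric scan: heat flow (W, endothermic positive) vs T."""

    temperature_C: np.ndarray
    heat_flow_W: np.ndarray
    sample_mass_kg: float
    heating_rate_K_per_min: float
    water_mass_fraction: float = 0.0

    def __post_init__(self):
        t = np.asarray(self.temperature_C, dtype=float)
        phi = np.asarray(self.heat_flow_W, dtype=float)
        if t.ndim != 1 or t.shape != phi.shape:
            raise ValueError("temperature and heat flow must be 1-D and aligned")
        if not np.all(np.diff(t) > 0):
            raise ValueError("temperature grid must be strictly increasing")
        if self.sample_mass_kg <= 0:
            raise ValueError("sample mass must be positive")
        if self.heating_rate_K_per_min <= 0:
            raise ValueError("heating rate must be positive")
        object.__setattr__(self, "temperature_C", t)
        object.__setattr__(self, "heat_flow_W", phi)


@dataclass(frozen=True)
class CpPoint:
    temperature_C: float
    water_mass_fraction: float
    cp_J_per_kgK: float


@dataclass(frozen=True)
class CpLinearModel:
    """cp = intercept + slope * T at one fixed water mass fraction."""

    intercept: float
    slope_per_degC: float
    water_mass_fraction: float
    valid_T_range: tuple[float, float]
    r_squared: float = float("nan")

    def predict(self, temperature_C):
        return self.intercept + self.slope_per_degC * np.asarray(temperature_C, float)


@dataclass(frozen=True)
class CpMlrModel:
    """cp = y0 + a*Xw + b*T (J kg^-1 K^-1), with fit diagnostics."""

    y0: float
    a_Xw: float
    b_T: float
    r_squared: float = float("nan")
    standard_error: float = float("nan")
    valid_Xw_range: tuple[float, float] = (0.6, 0.7)
    valid_T_range: tuple[float, float] = (40.0, 115.0)


def cp_from_heatflow(
    sample: CpScan,
    blank: CpScan,
    water_reference: CpScan,
    water_cp_lit: Callable = water_cp_literature,
) -> list[CpPoint]:
    """Blank-corrected, water-calibrated cp points on the overlapping T range.

    The water reference scan is reduced the same way as the sample
    ((phi - phi_blank)/(m*beta)); its ratio to the literature curve gives
    k(T), interpolated linearly between reference grid points.
    """
    lo = max(sample.temperature_C[0], blank.temperature_C[0],
             water_reference.temperature_C[0])
    hi = min(sample.temperature_C[-1], blank.temperature_C[-1],
             water_reference.temperature_C[-1])
    if lo >= hi:
        raise ValueError("scans have no overlapping temperature range")

    mask = (sample.temperature_C >= lo) & (sample.temperature_C <= hi)
    t = sample.temperature_C[mask]

    def reduced(scan: CpScan, at: np.ndarray) -> np.ndarray:
        phi_b = np.interp(at, blank.temperature_C, blank.heat_flow_W)
        phi = np.interp(at, scan.temperature_C, scan.heat_flow_W)
        beta_K_per_s = scan.heating_rate_K_per_min / 60.0
        return (phi - phi_b) / (scan.sample_mass_kg * beta_K_per_s)

    cp_raw = reduced(sample, t)

    t_ref = water_reference.temperature_C
    ref_mask = (t_ref >= lo) & (t_ref <= hi)
    cp_water_meas = reduced(water_reference, t_ref[ref_mask])
    if np.any(cp_water_meas <= 0):
        raise ValueError("measured water reference cp is non-positive; "
                         "reference scan is corrupt")
    k_nodes = np.asarray(water_cp_lit(t_ref[ref_mask])) / cp_water_meas
    k = np.interp(t, t_ref[ref_mask], k_nodes)

    cp = cp_raw * k
    xw = sample.water_mass_fraction
    return [CpPoint(float(ti), xw, float(ci)) for ti, ci in zip(t, cp)]


def fit_cp_linear(points: Sequence[CpPoint]) -> CpLinearModel:
    """OLS of cp on temperature for points sharing one water fraction."""
    if len(points) < 2:
        raise ValueError("need at least two points")
    xw = {round(p.water_mass_fraction, 12) for p in points}
    if len(xw) != 1:
        raise ValueError("linear cp fit expects a single water mass fraction")
    t = np.array([p.temperature_C for p in points])
    y = np.array([p.cp_J_per_kgK for p in points])
    if np.unique(t).size < 2:
        raise ValueError("all temperatures identical: rank-deficient fit")
    X = sm.add_constant(t)
    res = sm.OLS(y, X).fit()
    return CpLinearModel(
        intercept=float(res.params[0]),
        slope_per_degC=float(res.params[1]),
        water_mass_fraction=points[0].water_mass_fraction,
        valid_T_range=(float(t.min()), float(t.max())),
        r_squared=float(res.rsquared),
    )


def fit_cp_mlr(points: Sequence[CpPoint]) -> CpMlrModel:
    """OLS of cp on (Xw, T) with intercept.

    The reported standard error is the residual standard error with
    denominator n - 3.
    """
    if len(points) < 4:
        raise ValueError("need at least four points")
    xw = np.array([p.water_mass_fraction for p in points])
    t = np.array([p.temperature_C for p in points])
    y = np.array([p.cp_J_per_kgK for p in points])
    if np.unique(xw).size < 2 or np.unique(t).size < 2:
        raise ValueError("need at least two distinct Xw and two distinct T")
    X = sm.add_constant(np.column_stack([xw, t]))
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("design matrix rank-deficient")
    res = sm.OLS(y, X).fit()
    return CpMlrModel(
        y0=float(res.params[0]),
        a_Xw=float(res.params[1]),
        b_T=float(res.params[2]),
        r_squared=float(res.rsquared),
        standard_error=float(np.sqrt(res.scale)),
        valid_Xw_range=(float(xw.min()), float(xw.max())),
        valid_T_range=(float(t.min()), float(t.max())),
    )


def predict_cp(model: CpMlrModel, water_mass_fraction, temperature_C,
               warn_extrapolation: bool = True):
    """Evaluate cp = y0 + a*Xw + b*T.

    Evaluation outside the validity box is allowed (the water-extrapolation
    check depends on it) but flagged with :class:`ExtrapolationWarning`.
    """
    xw = np.asarray(water_mass_fraction, dtype=float)
    t = np.asarray(temperature_C, dtype=float)
    if warn_extrapolation:
        xlo, xhi = model.valid_Xw_range
        tlo, thi = model.valid_T_range
        if np.any(xw < xlo) or np.any(xw > xhi) or np.any(t < tlo) or np.any(t > thi):
            warnings.warn(
                "cp evaluated outside fitted validity box "
                f"Xw in {model.valid_Xw_range}, T in {model.valid_T_range}",
                ExtrapolationWarning,
                stacklevel=2,
            )
    cp = model.y0 + model.a_Xw * xw + model.b_T * t
    return float(cp) if np.ndim(cp) == 0 else cp


def water_extrapolation_error(model: CpMlrModel, temperature_C,
                              water_cp_lit: Callable = water_cp_literature):
    """Relative error of the model extrapolated to pure water at T.

    Positive values mean the regression overshoots the reference water cp,
    the expected direction when protein cp data are extrapolated to Xw = 1.
    """
    lit = np.asarray(water_cp_lit(temperature_C), dtype=float)
    pred = predict_cp(model, 1.0, temperature_C, warn_extrapolation=False)
    err = (np.asarray(pred) - lit) / lit
    return float(err) if err.ndim == 0 else err
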