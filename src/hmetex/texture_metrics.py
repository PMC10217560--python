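"""Quantitative texture analysis of high-moisture extrudates.

Slice-shear-force (SSF) specimens are cut from the outer part and from the
middle of an extrudate, parallel (longitudinal) and perpendicular
(transverse) to the flow direction out of the cooling die.  In a
well-structured product the longitudinal cutting strength rises toward the
middle of the 60 mm wide strand — a parabolic profile frozen in from the
laminar flow in the cooling die — while the transverse strength stays flat.

The structuring index condenses this into one number:

    SI = F_l,middle / F_l,outer,

the ratio of longitudinal cutting strength at the middle to the mean over
the two outer specimens.  SI is unit-free and scale-invariant.  This module
also fits the quadratic lateral profile, summarises SI per sensory texture
class (one-way ANOVA with Tukey post-hoc), regresses SI on extruder system
parameters, and screens classes against process-response thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "SsfMeasurement",
    "StructuringIndexResult",
    "ProfileFit",
    "structuring_index",
    "structuring_index_from_measurements",
    "fit_quadratic_profile",
    "class_statistics",
    "si_parameter_regressions",
    "threshold_screen",
    "DEFAULT_THRESHOLDS",
]

SAMPLE_WIDTH_MM = 60.0

#: minimum material temperature (degC), pressure (bar) and SME (Wh/kg)
#: observed to accompany well-structured products
DEFAULT_THRESHOLDS = {"material_temperature_C": 117.0,
                      "pressure_bar": 9.0,
                      "SME_Wh_per_kg": 9.0}


@dataclass(frozen=True)
class SsfMeasurement:
    run_id: str
    position: str  # "outer" or "middle"
    orientation: str  # "longitudinal" or "transverse"
    cutting_strength_N: float
    replicate: int = 0
    x_mm: Optional[float] = None  # lateral coordinate across the width

    def __post_init__(self):
        if self.cutting_strength_N < 0:
            raise ValueError("cutting strength must be non-negative")
        if self.position not in ("outer", "middle"):
            raise ValueError(f"unknown position {self.position!r}")
        if self.orientation not in ("longitudinal", "transverse"):
            raise ValueError(f"unknown orientation {self.orientation!r}")


@dataclass(frozen=True)
class StructuringIndexResult:
    SI: float
    F_l_middle_N: float
    F_l_outer_N: float


@dataclass(frozen=True)
class ProfileFit:
    """Quadratic fit F(x) = c0 + c1 x + c2 x^2 of lateral cutting strength."""

    c0: float
    c1: float
    c2: float
    vertex_x_mm: Optional[float]
    vertex_force_N: Optional[float]
    r_squared: float
    parabolic: bool  # opens downward with an interior vertex


def structuring_index(F_l_middle_N: float,
                      F_l_outer_N: float) -> StructuringIndexResult:
    """SI from middle and (edge-averaged) outer longitudinal forces."""
    if F_l_middle_N <= 0 or F_l_outer_N <= 0:
        raise ValueError("cutting strengths must be positive")
    return StructuringIndexResult(F_l_middle_N / F_l_outer_N,
                                  F_l_middle_N, F_l_outer_N)


def structuring_index_from_measurements(
    measurements: Sequence[SsfMeasurement],
) -> StructuringIndexResult:
    """SI from raw longitudinal specimen records (replicates averaged)."""
    mid = [m.cutting_strength_N for m in measurements
           if m.orientation == "longitudinal" and m.position == "middle"]
    out = [m.cutting_strength_N for m in measurements
           if m.orientation == "longitudinal" and m.position == "outer"]
    if not mid or not out:
        raise ValueError("need longitudinal measurements at both positions")
    return structuring_index(float(np.mean(mid)), float(np.mean(out)))


def fit_quadratic_profile(points: Sequence[tuple[float, float]],
                          width_mm: float = SAMPLE_WIDTH_MM) -> ProfileFit:
    """Least-squares quadratic of cutting strength vs lateral position."""
    if len(points) < 4:
        raise ValueError("need at least four points")
    x = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    if np.unique(x).size < 3:
        raise ValueError("need at least three distinct lateral positions")
    X = sm.add_constant(np.column_stack([x, x ** 2]))
    res = sm.OLS(y, X).fit()
    c0, c1, c2 = (float(v) for v in res.params)
    if c2 != 0.0:
        vx = -c1 / (2.0 * c2)
        vy = c0 + c1 * vx + c2 * vx ** 2
    else:
        vx = vy = None
    parabolic = c2 < 0 and vx is not None and 0.0 < vx < width_mm
    return ProfileFit(c0, c1, c2, vx, vy, float(res.rsquared), parabolic)


def _si_frame(runs) -> pd.DataFrame:
    """Labelled runs with a numeric SI, as a tidy frame."""
    rows = [
        {"run_id": r.run_id, "texture_label": r.texture_label,
         "SI": r.structuring_index,
         "material_temperature_C": r.material_temperature_Tin_C,
         "pressure_bar": r.pressure_bar,
         "SME_Wh_per_kg": (None if r.SME_unmeasured
                           else r.SME_measured_Wh_per_kg)}
        for r in runs
    ]
    df = pd.DataFrame(rows)
    return df[df["SI"].notna()]


def class_statistics(runs) -> dict:
    """Per-class SI mean/SD/n, one-way ANOVA, and Tukey pairwise tests.

    Rows without a recorded SI are excluded.  SDs are sample standard
    deviations (n - 1 denominator).
    """
    df = _si_frame(runs)
    counts = df.groupby("texture_label")["SI"].count()
    usable = counts[counts >= 2].index
    if len(usable) < 2:
        raise ValueError("need at least two texture classes with >= 2 SI values")
    df = df[df["texture_label"].isin(usable)]

    summary = (
        df.groupby("texture_label")["SI"]
        .agg(mean="mean", sd=lambda s: s.std(ddof=1), n="count")
        .reset_index()
    )
    groups = [g["SI"].to_numpy() for _, g in df.groupby("texture_label")]
    F, p = stats.f_oneway(*groups)
    tukey = pairwise_tukeyhsd(df["SI"].to_numpy(),
                              df["texture_label"].to_numpy(), alpha=0.05)
    pairwise = pd.DataFrame(
        tukey.summary().data[1:], columns=tukey.summary().data[0]
    )
    return {"summary": summary, "anova_F": float(F), "anova_p": float(p),
            "pairwise": pairwise}


def si_parameter_regressions(runs, average_center_points: bool = False,
                             center_run_ids: Sequence[str] = ()) -> dict:
    """OLS of SI on extruder system parameters.

    Fits SI ~ Tin (simple), SI ~ Tin + pressure and SI ~ Tin + SME.
    ``average_center_points`` collapses the listed centre-point runs of a
    central composite design into their mean record first.
    """
    df = _si_frame(runs).dropna(subset=["material_temperature_C"])
    if average_center_points and center_run_ids:
        cp = df[df["run_id"].isin(center_run_ids)]
        rest = df[~df["run_id"].isin(center_run_ids)]
        if not cp.empty:
            mean_row = cp.drop(columns="run_id").mean(numeric_only=True)
            mean_row["run_id"] = "CP-mean"
            mean_row["texture_label"] = cp["texture_label"].iloc[0]
            df = pd.concat([rest, mean_row.to_frame().T], ignore_index=True)
            df = df.astype({"SI": float, "material_temperature_C": float})
    if len(df) < 3:
        raise ValueError("need at least three complete records")

    out = {}
    y = df["SI"].astype(float).to_numpy()
    t = df["material_temperature_C"].astype(float).to_numpy()
    res = sm.OLS(y, sm.add_constant(t)).fit()
    out["si_vs_temperature"] = {
        "intercept": float(res.params[0]), "slope": float(res.params[1]),
        "r_squared": float(res.rsquared), "n": int(len(df)),
    }
    for name, col in (("si_vs_temperature_pressure", "pressure_bar"),
                      ("si_vs_temperature_sme", "SME_Wh_per_kg")):
        sub = df.dropna(subset=[col])
        X = sm.add_constant(np.column_stack([
            sub["material_temperature_C"].astype(float),
            sub[col].astype(float),
        ]))
        r = sm.OLS(sub["SI"].astype(float).to_numpy(), X).fit()
        out[name] = {"r_squared": float(r.rsquared), "n": int(len(sub))}
    return out


def threshold_screen(runs, thresholds: Optional[dict] = None) -> pd.DataFrame:
    """Per-texture-class minima of the system responses vs thresholds.

    Returns one row per class with the minimum material temperature,
    pressure and SME, and a boolean per response for whether the class
    minimum clears the threshold.  SME values flagged as unmeasured are
    ignored; empty minima are reported as NaN.
    """
    thresholds = {**DEFAULT_THRESHOLDS, **(thresholds or {})}
    rows = []
    for r in runs:
        rows.append({
            "texture_label": r.texture_label,
            "material_temperature_C": r.material_temperature_Tin_C,
            "pressure_bar": r.pressure_bar,
            "SME_Wh_per_kg": (None if r.SME_unmeasured
                              else r.SME_measured_Wh_per_kg),
        })
    df = pd.DataFrame(rows)
    out = []
    for label, g in df.groupby("texture_label"):
        rec = {"texture_label": label}
        for col, thr in thresholds.items():
            vals = g[col].dropna()
            mn = float(vals.min()) if len(vals) else float("nan")
            rec[f"min_{col}"] = mn
            rec[f"min_{col}_above_threshold"] = bool(mn > thr) if mn == mn else None
        out.append(rec)
    return pd.DataFrame(out)
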