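"""Extrusion energy balance: mechanical, thermal and total enthalpy input.

For a twin-screw extruder at steady state the specific mechanical energy
(SME) follows the torque-based expression

    SME [Wh/kg] = (n / n_max) * ((Md - Md,unload) / 100) * P_max / mdot,

with screw speed n (1/min), net torque as a percentage of full scale,
maximum engine power P_max (W) and total mass flow mdot (kg/h).

At the die entrance the material has been heated from the feed temperature
T0 to the measured material temperature Tin.  Because the measured Tin
already reflects both barrel heating and viscous dissipation, the combined
mechanical-plus-thermal enthalpy rise is cp * (Tin - T0); this quantity is
stored as the specific thermal energy STE (J/g).  Adding the protein
melting enthalpy dH_m gives the total extrusion enthalpy

    dH_extruder = cp(Tbar) * (Tin - T0) / 1000 + dH_m   [J/g],

with cp evaluated at the mean temperature Tbar = (T0 + Tin)/2 by default
(the ``T0_only`` convention evaluates it at T0 instead, for use when Tin
is unknown a priori).  An SME term is deliberately NOT added on top: it is
already embodied in the measured Tin; a diagnostic flag exposes the
literal three-term sum for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .thermophysics import CpMlrModel, predict_cp

__all__ = [
    "ExtrusionRun",
    "EnergyBalance",
    "SmeNotMeasurableError",
    "WH_PER_KG_TO_J_PER_G",
    "N_MAX_DEFAULT",
    "P_MAX_DEFAULT",
    "T0_FEED_DEFAULT",
    "compute_sme",
    "compute_ste",
    "compute_extrusion_enthalpy",
]

#: 1 Wh/kg = 3.6 J/g
WH_PER_KG_TO_J_PER_G = 3.6

N_MAX_DEFAULT = 500.0  # 1/min, machine constant
P_MAX_DEFAULT = 8600.0  # W, machine constant
T0_FEED_DEFAULT = 20.0  # degC, feed temperature

TEXTURE_CLASSES = ("poorly-textured", "textured", "well-textured", "unknown")


class SmeNotMeasurableError(ValueError):
    """Torque data absent: SME is not computable (distinct from zero)."""


@dataclass
class ExtrusionRun:
    """One extrusion experiment: design factors, constants and responses."""

    run_id: str
    protein_id: str = ""
    screw_speed_n: float = float("nan")
    water_content_Xw: float = float("nan")  # wet-basis moisture fraction
    mass_flow_kg_per_h: float = float("nan")
    barrel_temperature_C: float = float("nan")
    torque_Md_pct: Optional[float] = None
    idle_torque_Md_unload_pct: Optional[float] = None
    n_max: float = N_MAX_DEFAULT
    P_max_W: float = P_MAX_DEFAULT
    T0_feed_C: float = T0_FEED_DEFAULT
    material_temperature_Tin_C: Optional[float] = None
    pressure_bar: Optional[float] = None
    SME_measured_Wh_per_kg: Optional[float] = None
    SME_unmeasured: bool = False  # True when the logged SME zero means "not recordable"
    texture_label: str = "unknown"
    structuring_index: Optional[float] = None

    def __post_init__(self):
        if self.texture_label not in TEXTURE_CLASSES:
            raise ValueError(f"unknown texture label {self.texture_label!r}")
        if self.screw_speed_n == self.screw_speed_n and self.screw_speed_n > self.n_max:
            raise ValueError("screw speed exceeds machine maximum")
        if self.mass_flow_kg_per_h == self.mass_flow_kg_per_h and self.mass_flow_kg_per_h <= 0:
            raise ValueError("mass flow must be positive")


@dataclass(frozen=True)
class EnergyBalance:
    SME_Wh_per_kg: Optional[float]
    STE_J_per_g: float
    dH_extruder_J_per_g: float
    cp_used_J_per_kgK: float
    T_mean_used_C: float


def compute_sme(run: ExtrusionRun) -> float:
    """Specific mechanical energy of a run, Wh/kg, from torque readings."""
    if run.torque_Md_pct is None or run.idle_torque_Md_unload_pct is None:
        raise SmeNotMeasurableError(
            f"run {run.run_id}: torque not recorded, SME not computable"
        )
    net = run.torque_Md_pct - run.idle_torque_Md_unload_pct
    if net < 0:
        raise ValueError("net torque negative (Md < Md,unload)")
    return (run.screw_speed_n / run.n_max) * (net / 100.0) * run.P_max_W \
        / run.mass_flow_kg_per_h


def compute_ste(
    cp_model: CpMlrModel,
    water_mass_fraction: float,
    T0_C: float,
    Tin_C: float,
    convention: str = "mean_T",
) -> tuple[float, float, float]:
    """Specific thermal energy cp*(Tin - T0) in J/g.

    Returns ``(STE, cp_used, T_mean_used)``.  ``convention`` selects the
    temperature at which cp is evaluated: the midpoint of [T0, Tin]
    (default) or T0 alone.
    """
    if Tin_C < T0_C:
        raise ValueError("material temperature below feed temperature")
    if convention == "mean_T":
        t_eval = 0.5 * (T0_C + Tin_C)
    elif convention == "T0_only":
        t_eval = T0_C
    else:
        raise ValueError(f"unknown cp convention {convention!r}")
    cp = predict_cp(cp_model, water_mass_fraction, t_eval,
                    warn_extrapolation=False)
    ste = cp * (Tin_C - T0_C) / 1000.0
    return ste, cp, t_eval


def compute_extrusion_enthalpy(
    STE_J_per_g: float,
    dH_m_J_per_g: float,
    SME_Wh_per_kg: Optional[float] = None,
    include_sme_term: bool = False,
) -> float:
    """Total extrusion enthalpy dH_extruder = STE + dH_m, J/g.

    ``include_sme_term`` is a diagnostic mode that adds the mechanical
    term a second time (converted at 3.6 J/g per Wh/kg); it double-counts
    dissipation already contained in the measured material temperature and
    exists only for comparison.
    """
    if dH_m_J_per_g < 0:
        raise ValueError("melting enthalpy must be non-negative")
    total = STE_J_per_g + dH_m_J_per_g
    if include_sme_term:
        total += (SME_Wh_per_kg or 0.0) * WH_PER_KG_TO_J_PER_G
    return total
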