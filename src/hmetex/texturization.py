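"""Texturization indicator and the extrusion melting hurdle.

The texturization indicator compares the enthalpy a protein-water mass
actually receives in the extruder with the enthalpy a DSC scan says is
needed to form a complete protein melt:

    TI = dH_extruder / dH_DSC.

Rounded to two decimals, TI < 1 marks a poorly-textured product, TI = 1 a
textured one and TI > 1 a well-textured one (a meat analog with defined
fibrous structure); TI between about 1.05 and 1.1 is the advisory band for
robust texturization.

Setting TI = 1 and solving for the material temperature gives the
extrusion melting hurdle (EMH): the minimum die-entrance temperature at
which a complete melt can form,

    Tin = (TI_target * dH_DSC - dH_m) * 1000 / cp + T0.

Under the mean-temperature cp convention cp depends on Tin itself, so the
equation is solved by fixed-point iteration (the contraction constant
b_T * dH / cp^2 is small for realistic parameters); the T0-only
convention admits the closed form directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .energetics import compute_extrusion_enthalpy, compute_ste
from .phase_transition import TransitionResult
from .thermophysics import CpMlrModel, predict_cp

__all__ = [
    "TexturizationAssessment",
    "ROBUST_TI_BAND",
    "texturization_indicator",
    "classify_ti",
    "assess_run",
    "minimum_texturization_temperature",
    "round_trip_consistency",
]

#: advisory band for robust texturization (not a class boundary)
ROBUST_TI_BAND = (1.05, 1.10)


@dataclass(frozen=True)
class TexturizationAssessment:
    TI: float
    TI_rounded: float
    predicted_class: str
    EMH_temperature_C: Optional[float] = None
    convention: str = "mean_T"
    protein_id: str = ""
    run_id: str = ""


def texturization_indicator(dH_extruder_J_per_g: float,
                            dH_DSC_J_per_g: float) -> float:
    """TI = dH_extruder / dH_DSC."""
    if dH_DSC_J_per_g <= 0:
        raise ValueError("dH_DSC must be positive")
    return dH_extruder_J_per_g / dH_DSC_J_per_g


def classify_ti(TI: float, decimals: int = 2) -> str:
    """Texture class from TI rounded to ``decimals`` places."""
    r = round(TI, decimals)
    if r < 1.0:
        return "poorly-textured"
    if r > 1.0:
        return "well-textured"
    return "textured"


def assess_run(
    cp_model: CpMlrModel,
    water_mass_fraction: float,
    transition: TransitionResult,
    Tin_C: float,
    T0_C: float = 20.0,
    convention: str = "mean_T",
    protein_id: str = "",
    run_id: str = "",
) -> TexturizationAssessment:
    """TI and texture class for one run with measured material temperature."""
    ste, _, _ = compute_ste(cp_model, water_mass_fraction, T0_C, Tin_C,
                            convention)
    dh_ext = compute_extrusion_enthalpy(ste, transition.dH_m_J_per_g)
    ti = texturization_indicator(dh_ext, transition.dH_DSC_J_per_g)
    return TexturizationAssessment(
        TI=ti,
        TI_rounded=round(ti, 2),
        predicted_class=classify_ti(ti),
        convention=convention,
        protein_id=protein_id,
        run_id=run_id,
    )


def minimum_texturization_temperature(
    cp_model: CpMlrModel,
    water_mass_fraction: float,
    transition: TransitionResult,
    T0_C: float = 20.0,
    TI_target: float = 1.0,
    convention: str = "mean_T",
    tol_C: float = 1e-6,
    max_iter: int = 100,
) -> float:
    """Solve for the EMH temperature at which TI reaches ``TI_target``.

    Fixed-point iteration from the T0-evaluated closed form; falls back to
    bisection on the residual if the iteration oscillates.
    """
    dH_needed = TI_target * transition.dH_DSC_J_per_g - transition.dH_m_J_per_g
    if dH_needed < 0:
        raise ValueError(
            "TI_target * dH_DSC < dH_m: target would imply melting without heating"
        )

    def cp_at(Tin: float) -> float:
        t_eval = 0.5 * (T0_C + Tin) if convention == "mean_T" else T0_C
        return predict_cp(cp_model, water_mass_fraction, t_eval,
                          warn_extrapolation=False)

    if convention == "T0_only":
        return T0_C + dH_needed * 1000.0 / cp_at(T0_C)

    tin = T0_C + dH_needed * 1000.0 / cp_at(T0_C)
    prev_step = None
    for _ in range(max_iter):
        new = T0_C + dH_needed * 1000.0 / cp_at(tin)
        step = new - tin
        if prev_step is not None and step * prev_step < 0 and abs(step) >= abs(prev_step):
            return _bisect_emh(cp_at, dH_needed, T0_C, tol_C)
        tin = new
        if abs(step) < tol_C:
            return tin
        prev_step = step
    raise RuntimeError("EMH fixed-point iteration did not converge")


def _bisect_emh(cp_at, dH_needed: float, T0_C: float, tol_C: float) -> float:
    def resid(tin: float) -> float:
        return T0_C + dH_needed * 1000.0 / cp_at(tin) - tin

    lo, hi = T0_C, 250.0
    if resid(hi) > 0:
        raise RuntimeError("EMH exceeds 250 degC search bracket")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if resid(mid) > 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol_C:
            break
    return 0.5 * (lo + hi)


def round_trip_consistency(
    cp_model: CpMlrModel,
    water_mass_fraction: float,
    transition: TransitionResult,
    EMH_C: float,
    T0_C: float = 20.0,
    convention: str = "mean_T",
) -> float:
    """TI evaluated at Tin = EMH; equals the solver's target by construction."""
    a = assess_run(cp_model, water_mass_fraction, transition, EMH_C, T0_C,
                   convention)
    return a.TI
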