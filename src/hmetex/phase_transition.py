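"""Denaturation endotherm analysis of DSC thermograms.

A hydrated globular protein scanned from ~20 to 170 degC shows one broad
endothermic peak where the storage proteins unfold ("melt").  Three
temperatures characterise it — the onset of heat-flow deviation T_onset,
the peak maximum T_m and the end temperature T_end — plus two enthalpies:

* dH_m   — the peak area above a linear baseline, integrated between
           T_onset and T_end; the latent heat of the unfolding transition.
* dH_DSC — the total heat applied between a reference temperature T0
           (20 degC by default) and T_end, i.e. sensible heating plus the
           endotherm, with no baseline subtraction.  This is the enthalpy
           a melt-forming process has to deliver.

The heat flow is stored per unit sample mass (W/g, endothermic positive),
so dividing the temperature integral by the heating rate (K/s) yields J/g.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "Thermogram",
    "TransitionResult",
    "NoTransitionError",
    "detect_transition",
    "melting_enthalpy",
    "total_dsc_enthalpy",
    "analyze_thermogram",
]

DEFAULT_T0_REF = 20.0
DEFAULT_ONSET_FRACTION = 0.01


class NoTransitionError(ValueError):
    """The thermogram contains no resolvable endothermic peak."""


@dataclass(frozen=True)
class Thermogram:
    """Mass-specific DSC scan: heat flow (W/g, endothermic positive) vs T."""

    temperature_C: np.ndarray
    specific_heat_flow_W_per_g: np.ndarray
    heating_rate_K_per_min: float
    sample_mass_g: float = 1.0
    water_mass_fraction: float = 0.6

    def __post_init__(self):
        t = np.asarray(self.temperature_C, dtype=float)
        phi = np.asarray(self.specific_heat_flow_W_per_g, dtype=float)
        if t.ndim != 1 or t.shape != phi.shape:
            raise ValueError("temperature and heat flow must be 1-D and aligned")
        if not np.all(np.diff(t) > 0):
            raise ValueError("temperature grid must be strictly increasing")
        if self.heating_rate_K_per_min <= 0:
            raise ValueError("heating rate must be positive")
        if self.sample_mass_g <= 0:
            raise ValueError("sample mass must be positive")
        object.__setattr__(self, "temperature_C", t)
        object.__setattr__(self, "specific_heat_flow_W_per_g", phi)

    @property
    def heating_rate_K_per_s(self) -> float:
        return self.heating_rate_K_per_min / 60.0


@dataclass(frozen=True)
class TransitionResult:
    T_onset_C: float
    T_m_C: float
    T_end_C: float
    dH_m_J_per_g: float
    dH_DSC_J_per_g: float
    T0_ref_C: float = DEFAULT_T0_REF

    def __post_init__(self):
        if not (self.T_onset_C < self.T_m_C < self.T_end_C):
            raise ValueError("require T_onset < T_m < T_end")
        if self.dH_m_J_per_g < 0:
            raise ValueError("dH_m must be non-negative")


class _Baseline:
    """Straight line through the window means of the signal."""

    def __init__(self, t1, y1, t2, y2):
        self.slope = (y2 - y1) / (t2 - t1)
        self.intercept = y1 - self.slope * t1

    def __call__(self, temperature_C):
        return self.intercept + self.slope * np.asarray(temperature_C, float)


def _window_mask(t: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    mask = (t >= lo) & (t <= hi)
    if mask.sum() < 5:
        raise ValueError(f"window {window} covers fewer than 5 grid points")
    return mask


def detect_transition(
    tg: Thermogram,
    pre_window: tuple[float, float],
    post_window: tuple[float, float],
    onset_fraction: float = DEFAULT_ONSET_FRACTION,
):
    """Locate the endotherm between two peak-free baseline windows.

    The baseline is the straight line through the least-squares means of
    the signal in the two windows.  T_m is the temperature of the maximum
    baseline-subtracted signal; T_onset / T_end are found by scanning
    outward from T_m to the first grid points at which the subtracted
    signal falls to ``onset_fraction`` of the peak height.

    Returns ``(T_onset, T_m, T_end, baseline)``; the baseline is a callable
    reusable by :func:`melting_enthalpy`.

    Raises :class:`NoTransitionError` when the peak height does not exceed
    three times the pre-window residual standard deviation.
    """
    t = tg.temperature_C
    phi = tg.specific_heat_flow_W_per_g
    pre = _window_mask(t, pre_window)
    post = _window_mask(t, post_window)

    baseline = _Baseline(t[pre].mean(), phi[pre].mean(),
                         t[post].mean(), phi[post].mean())
    excess = phi - baseline(t)

    noise_sd = float(np.std(excess[pre], ddof=1))
    i_peak = int(np.argmax(excess))
    height = float(excess[i_peak])
    # floor guards against a numerically flat signal (sd == 0 exactly)
    floor = 1e-9 * max(float(np.max(np.abs(phi))), 1e-30)
    if height <= 3.0 * noise_sd or height <= floor:
        raise NoTransitionError("no transition detected")

    thr = onset_fraction * height
    i = i_peak
    while i > 0 and excess[i - 1] > thr:
        i -= 1
    j = i_peak
    n = excess.size
    while j < n - 1 and excess[j + 1] > thr:
        j += 1
    T_onset, T_m, T_end = float(t[i]), float(t[i_peak]), float(t[j])

    for name, window in (("pre", pre_window), ("post", post_window)):
        if window[1] > T_onset and window[0] < T_end:
            raise ValueError(
                f"{name} window {window} overlaps the detected peak "
                f"[{T_onset:.1f}, {T_end:.1f}] degC"
            )
    return T_onset, T_m, T_end, baseline


def _integrate(tg: Thermogram, y: np.ndarray, lo: float, hi: float) -> float:
    """Trapezoidal integral of y dT / beta over [lo, hi], with the bounds
    inserted by linear interpolation."""
    t = tg.temperature_C
    if lo < t[0] or hi > t[-1]:
        raise ValueError("integration bounds outside the temperature grid")
    if lo > hi:
        raise ValueError("lower bound exceeds upper bound")
    inner = (t > lo) & (t < hi)
    tt = np.concatenate([[lo], t[inner], [hi]])
    yy = np.concatenate([[np.interp(lo, t, y)], y[inner], [np.interp(hi, t, y)]])
    return float(np.trapezoid(yy, tt) / tg.heating_rate_K_per_s)


def melting_enthalpy(tg: Thermogram, T_onset: float, T_end: float,
                     baseline) -> float:
    """Peak area above the baseline over [T_onset, T_end], in J/g.

    Signed integration: negative partial areas are kept.
    """
    excess = tg.specific_heat_flow_W_per_g - baseline(tg.temperature_C)
    return _integrate(tg, excess, T_onset, T_end)


def total_dsc_enthalpy(tg: Thermogram, T0: float, T_end: float) -> float:
    """Total applied enthalpy (no baseline subtraction) over [T0, T_end], J/g."""
    return _integrate(tg, tg.specific_heat_flow_W_per_g, T0, T_end)


def analyze_thermogram(
    tg: Thermogram,
    pre_window: tuple[float, float] = (25.0, 70.0),
    post_window: tuple[float, float] = (150.0, 168.0),
    onset_fraction: float = DEFAULT_ONSET_FRACTION,
    T0_ref: float = DEFAULT_T0_REF,
) -> TransitionResult:
    """Full endotherm characterisation of one thermogram.

    Composes :func:`detect_transition`, :func:`melting_enthalpy` and
    :func:`total_dsc_enthalpy` with the default 20-170 degC evaluation
    conventions.  The default windows suit hydrated plant-protein scans
    whose endotherm lies between roughly 80 and 135 degC.
    """
    T_onset, T_m, T_end, baseline = detect_transition(
        tg, pre_window, post_window, onset_fraction
    )
    dH_m = melting_enthalpy(tg, T_onset, T_end, baseline)
    dH_DSC = total_dsc_enthalpy(tg, T0_ref, T_end)
    return TransitionResult(T_onset, T_m, T_end, dH_m, dH_DSC, T0_ref)
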