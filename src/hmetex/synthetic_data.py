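"""Ground-truth generators for every input the pipeline consumes.

Instrument data (microcalorimeter cp scans, DSC thermograms,
slice-shear-force profiles) and extrusion campaigns are simulated from
known parameters so that each analysis stage can be tested as a parameter
recovery problem.  All generators are pure functions of their parameters
and a seed.

The extrusion response model used here is openly synthetic test plumbing:
net torque rises with dry-matter content and screw speed, the material
temperature tracks the barrel setpoint plus viscous dissipation minus a
moisture penalty, and pressure falls with moisture and rises with
throughput.  Its coefficients are chosen so the simulated response ranges
overlap realistic pilot-scale campaigns (material temperature roughly
90-140 degC, SME 0-35 Wh/kg, pressure 1-30 bar); it claims no rheological
fidelity.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .energetics import ExtrusionRun, compute_sme
from .phase_transition import Thermogram, TransitionResult
from .texture_metrics import SsfMeasurement
from .texturization import assess_run
from .thermophysics import CpMlrModel, CpScan, predict_cp, water_cp_literature

__all__ = [
    "ProteinSpec",
    "CcdDesign",
    "ExtrusionResponseParams",
    "default_protein_specs",
    "generate_ccd",
    "simulate_cp_scans",
    "simulate_thermogram",
    "simulate_extrusion_runs",
    "simulate_ssf_profile",
]


@dataclass(frozen=True)
class ProteinSpec:
    """Generator truth for one protein: cp plane plus endotherm parameters."""

    name: str
    cp_model: CpMlrModel
    transition: TransitionResult
    peak_shape: str = "skewed"  # or "gaussian"
    peak_sharpness: float = 1.5

    def __post_init__(self):
        if self.peak_shape not in ("skewed", "gaussian"):
            raise ValueError(f"unknown peak shape {self.peak_shape!r}")


@dataclass(frozen=True)
class CcdDesign:
    """A face-or-star central composite design over k factors."""

    factor_names: tuple[str, ...]
    centres: tuple[float, ...]
    half_ranges: tuple[float, ...]
    alpha: float
    n_center: int
    rows: tuple[dict, ...]

    def as_arrays(self) -> np.ndarray:
        return np.array([[r[f] for f in self.factor_names] for r in self.rows])


def default_protein_specs() -> dict[str, ProteinSpec]:
    """Specs for the three packaged reference proteins (60% moisture)."""
    from .io import load_cp_models, load_transitions  # lazy: io reads fixtures

    models = load_cp_models()
    transitions = load_transitions()
    return {
        name: ProteinSpec(name=name, cp_model=models[name],
                          transition=transitions[name])
        for name in models
    }


def generate_ccd(
    centres: dict[str, float],
    half_ranges: dict[str, float],
    alpha: float = 1.5,
    n_center: int = 3,
) -> CcdDesign:
    """Full 2^k factorial plus 2k axial points plus centre replicates.

    Axial points sit at centre +/- alpha * half_range.  Rows are ordered
    deterministically: factorial block (levels cycling fastest over the
    last factor), then axial block (low then high per factor, in factor
    order), then the centre replicates.
    """
    names = tuple(centres)
    if len(names) < 2:
        raise ValueError("need at least two factors")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    for f in names:
        if half_ranges[f] <= 0:
            raise ValueError(f"non-positive half-range for factor {f!r}")

    rows: list[dict] = []
    for combo in itertools.product((-1.0, 1.0), repeat=len(names)):
        rows.append({f: centres[f] + c * half_ranges[f]
                     for f, c in zip(names, combo)})
    for f in names:
        for sign in (-1.0, 1.0):
            row = dict(centres)
            row[f] = centres[f] + sign * alpha * half_ranges[f]
            rows.append(row)
    rows.extend(dict(centres) for _ in range(n_center))

    return CcdDesign(
        factor_names=names,
        centres=tuple(centres[f] for f in names),
        half_ranges=tuple(half_ranges[f] for f in names),
        alpha=alpha,
        n_center=n_center,
        rows=tuple(rows),
    )


def simulate_cp_scans(
    cp_true,
    water_mass_fraction: float,
    T_range: tuple[float, float] = (40.0, 115.0),
    grid_step: float = 0.5,
    beta_K_per_min: float = 0.2,
    sample_mass_kg: float = 6.5e-4,
    instrument_gain: float = 1.0,
    noise_sd_W: float = 0.0,
    seed: int = 0,
) -> tuple[CpScan, CpScan, CpScan]:
    """Forward-simulate a (sample, blank, water reference) scan triple.

    ``instrument_gain`` multiplies all true heat flows, emulating a
    miscalibrated sensor; the water-reference correction in
    :func:`~hmetex.thermophysics.cp_from_heatflow` removes it exactly.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(T_range[0], T_range[1] + grid_step / 2, grid_step)
    beta_s = beta_K_per_min / 60.0
    blank_flow = 1e-4 + 2e-7 * t  # small instrument baseline, W

    def scan(cp_func, xw):
        phi = blank_flow + instrument_gain * np.asarray(cp_func(t)) \
            * sample_mass_kg * beta_s
        if noise_sd_W > 0:
            phi = phi + rng.normal(0.0, noise_sd_W, t.size)
        return CpScan(t, phi, sample_mass_kg, beta_K_per_min, xw)

    sample = scan(cp_true, water_mass_fraction)
    blank = CpScan(t, blank_flow.copy(), sample_mass_kg, beta_K_per_min, 0.0)
    water = scan(water_cp_literature, 1.0)
    return sample, blank, water


def _peak_shape(t: np.ndarray, spec: ProteinSpec) -> np.ndarray:
    """Unit-amplitude endotherm supported on [T_onset, T_end], mode at T_m."""
    tr = spec.transition
    a, m, b = tr.T_onset_C, tr.T_m_C, tr.T_end_C
    u = np.clip((t - a) / (b - a), 0.0, 1.0)
    um = (m - a) / (b - a)
    if spec.peak_shape == "skewed":
        s = spec.peak_sharpness
        p, q = s * um, s * (1.0 - um)
        with np.errstate(divide="ignore", invalid="ignore"):
            shape = np.where((u > 0) & (u < 1), u ** p * (1.0 - u) ** q, 0.0)
    else:
        sigma = (b - a) / 6.0
        shape = np.exp(-0.5 * ((t - m) / sigma) ** 2)
        edge = max(np.exp(-0.5 * ((a - m) / sigma) ** 2),
                   np.exp(-0.5 * ((b - m) / sigma) ** 2))
        shape = np.clip(shape - edge, 0.0, None)
        shape[(t < a) | (t > b)] = 0.0
    return shape


def simulate_thermogram(
    spec: ProteinSpec,
    T_range: tuple[float, float] = (10.0, 170.0),
    grid_step: float = 0.05,
    beta_K_per_min: float = 5.0,
    noise_sd_W_per_g: float = 0.0,
    seed: int = 0,
) -> Thermogram:
    """DSC forward model: cp-plane baseline plus a rescaled endotherm.

    The peak amplitude is normalised numerically so that its trapezoidal
    temperature integral divided by the heating rate equals the spec's
    dH_m on the generated grid.
    """
    tr = spec.transition
    t = np.arange(T_range[0], T_range[1] + grid_step / 2, grid_step)
    if t[0] > min(tr.T0_ref_C, tr.T_onset_C) or t[-1] < tr.T_end_C:
        raise ValueError("grid must cover [T0_ref, T_end]")
    n_peak = int(np.sum((t >= tr.T_onset_C) & (t <= tr.T_end_C)))
    if n_peak < 20:
        raise ValueError("grid too coarse: fewer than 20 points across the peak")

    beta_s = beta_K_per_min / 60.0
    cp = predict_cp(spec.cp_model, spec_water(spec), t,
                    warn_extrapolation=False)
    baseline = cp / 1000.0 * beta_s  # W/g

    shape = _peak_shape(t, spec)
    if tr.dH_m_J_per_g > 0:
        area = np.trapezoid(shape, t) / beta_s
        peak = shape * (tr.dH_m_J_per_g / area)
    else:
        peak = np.zeros_like(shape)

    signal = baseline + peak
    if noise_sd_W_per_g > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, noise_sd_W_per_g, t.size)
    return Thermogram(t, signal, beta_K_per_min,
                      water_mass_fraction=spec_water(spec))


def spec_water(spec: ProteinSpec) -> float:
    """Water mass fraction a spec's thermograms are generated at."""
    return spec.cp_model.valid_Xw_range[0]


@dataclass(frozen=True)
class ExtrusionResponseParams:
    """Coefficients of the synthetic extruder response surface."""

    torque_intercept_pct: float = -14.0
    torque_dry_matter_pct: float = 40.0  # per unit (1 - Xw)
    torque_speed_pct_per_rpm: float = 0.004
    torque_flow_pct_per_kgh: float = 0.10
    idle_torque_pct: float = 5.0
    tin_offset_C: float = 25.0
    tin_barrel_gain: float = 0.65
    tin_dissipation_C_per_Whkg: float = 0.30
    tin_moisture_penalty_C_per_pct: float = 1.0
    pressure_base_bar: float = 9.0
    pressure_moisture_bar_per_pct: float = 1.2
    pressure_flow_bar_per_kgh: float = 0.5
    noise_sd_Tin_C: float = 0.0
    noise_sd_torque_pct: float = 0.0
    noise_sd_pressure_bar: float = 0.0


def simulate_extrusion_runs(
    design: CcdDesign,
    spec: ProteinSpec,
    params: ExtrusionResponseParams = ExtrusionResponseParams(),
    seed: int = 0,
) -> list[ExtrusionRun]:
    """Simulate an extrusion campaign over a CCD.

    Each run carries simulated torque, SME, material temperature and
    pressure, plus a ground-truth texture label obtained by running the
    texturization-indicator pipeline on the simulated material temperature
    with the spec's own cp model and transition.
    """
    rng = np.random.default_rng(seed)
    runs = []
    for i, row in enumerate(design.rows, start=1):
        n = row["screw_speed_rpm"]
        moist_pct = row["moisture_pct"]
        mdot = row["mass_flow_kg_per_h"]
        barrel = row["barrel_temperature_C"]
        xw = moist_pct / 100.0

        net_torque = (params.torque_intercept_pct
                      + params.torque_dry_matter_pct * (1.0 - xw)
                      + params.torque_speed_pct_per_rpm * n
                      - params.torque_flow_pct_per_kgh * mdot)
        if params.noise_sd_torque_pct > 0:
            net_torque += rng.normal(0.0, params.noise_sd_torque_pct)
        net_torque = max(net_torque, 0.0)
        unmeasured = net_torque == 0.0

        run = ExtrusionRun(
            run_id=f"sim-{i:02d}",
            protein_id=spec.name,
            screw_speed_n=n,
            water_content_Xw=xw,
            mass_flow_kg_per_h=mdot,
            barrel_temperature_C=barrel,
            torque_Md_pct=params.idle_torque_pct + net_torque,
            idle_torque_Md_unload_pct=params.idle_torque_pct,
            SME_unmeasured=unmeasured,
        )
        sme = compute_sme(run)
        run.SME_measured_Wh_per_kg = sme

        tin = (params.tin_offset_C + params.tin_barrel_gain * barrel
               + params.tin_dissipation_C_per_Whkg * sme
               - params.tin_moisture_penalty_C_per_pct * (moist_pct - 65.0))
        if params.noise_sd_Tin_C > 0:
            tin += rng.normal(0.0, params.noise_sd_Tin_C)
        run.material_temperature_Tin_C = tin

        pressure = (params.pressure_base_bar
                    - params.pressure_moisture_bar_per_pct * (moist_pct - 65.0)
                    + params.pressure_flow_bar_per_kgh * mdot)
        if params.noise_sd_pressure_bar > 0:
            pressure += rng.normal(0.0, params.noise_sd_pressure_bar)
        run.pressure_bar = max(pressure, 0.5)

        assessment = assess_run(spec.cp_model, xw, spec.transition,
                                Tin_C=max(tin, run.T0_feed_C),
                                protein_id=spec.name, run_id=run.run_id)
        run.texture_label = assessment.predicted_class
        runs.append(run)
    return runs


def simulate_ssf_profile(
    SI_target: float,
    base_force_N: float = 10.0,
    width_mm: float = 60.0,
    noise_sd_N: float = 0.0,
    n_replicates: int = 5,
    seed: int = 0,
    run_id: str = "sim-ssf",
) -> list[SsfMeasurement]:
    """Slice-shear-force specimens from a parabolic longitudinal profile.

    Longitudinal forces follow a downward parabola through the outer
    specimen centres (x = width/6 from each edge... concretely x = 10 and
    50 mm on a 60 mm strand) at ``base_force_N`` and the middle (x = 30)
    at ``SI_target * base_force_N``; transverse forces are flat at the
    base force.  The middle/outer ratio of the noise-free longitudinal
    specimens therefore equals ``SI_target`` exactly.
    """
    if SI_target < 1.0:
        raise ValueError("SI_target must be >= 1 for a parabolic profile")
    rng = np.random.default_rng(seed)
    half = width_mm / 2.0
    x_outer = (width_mm / 6.0, width_mm - width_mm / 6.0)
    x_mid = half

    def force(x):
        # parabola with F(x_outer) = base, F(mid) = SI * base
        span = (x_mid - x_outer[0]) ** 2
        return base_force_N * (SI_target - (SI_target - 1.0)
                               * (x - x_mid) ** 2 / span)

    out = []
    for rep in range(n_replicates):
        for orientation in ("longitudinal", "transverse"):
            for pos, x in (("outer", x_outer[0]), ("middle", x_mid),
                           ("outer", x_outer[1])):
                f = force(x) if orientation == "longitudinal" else base_force_N
                if noise_sd_N > 0:
                    f += rng.normal(0.0, noise_sd_N)
                out.append(SsfMeasurement(run_id, pos, orientation,
                                          max(f, 0.0), rep, x))
    return out
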