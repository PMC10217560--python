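"""CSV readers/writers, packaged reference fixtures, configuration, and
the end-to-end pipeline driver.

All files are plain comma-separated text with a header row, "." decimal
and UTF-8 encoding; lines starting with ``#`` are provenance comments.
The packaged fixtures under ``hmetex/data`` transcribe the reference
campaign for three commercial plant proteins (a soy concentrate, a soy
isolate and a pea isolate) plus the 27-run screening campaign of the
benchmark soy concentrate.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, fields
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .energetics import (
    N_MAX_DEFAULT,
    P_MAX_DEFAULT,
    T0_FEED_DEFAULT,
    ExtrusionRun,
)
from .phase_transition import Thermogram, TransitionResult
from .texturization import (
    assess_run,
    classify_ti,
    minimum_texturization_temperature,
)
from .thermophysics import CpMlrModel, CpPoint

__all__ = [
    "PipelineConfig",
    "fixture_path",
    "load_design",
    "load_validation_design",
    "load_runs_table",
    "save_runs_table",
    "load_cp_models",
    "load_transitions",
    "load_emh_reference",
    "load_validation_runs",
    "load_cp_points",
    "save_cp_points",
    "load_thermogram",
    "save_thermogram",
    "run_full_pipeline",
]

logger = logging.getLogger("hmetex")

_RUNS_COLUMNS = ["run_id", "X1_rpm", "X2_moisture_pct", "X3_kg_per_h",
                 "X4_barrel_C", "Y1_material_C", "Y2_pressure_bar",
                 "Y3_SME_Wh_per_kg", "SI", "texture_label"]


@dataclass
class PipelineConfig:
    """Conventions and machine constants for the assessment pipeline."""

    convention: str = "mean_T"  # or "T0_only"
    T0_feed_C: float = T0_FEED_DEFAULT
    TI_target: float = 1.0
    rounding_decimals: int = 2
    onset_fraction: float = 0.01
    n_max: float = N_MAX_DEFAULT
    P_max_W: float = P_MAX_DEFAULT
    seed: int = 0

    def __post_init__(self):
        if self.convention not in ("mean_T", "T0_only"):
            raise ValueError(f"unknown convention {self.convention!r}")
        if not 0 < self.onset_fraction < 1:
            raise ValueError("onset_fraction must lie in (0, 1)")
        if self.TI_target <= 0 or self.T0_feed_C < 0 or self.n_max <= 0 \
                or self.P_max_W <= 0 or self.rounding_decimals < 0:
            raise ValueError("config value out of range")

    def to_text(self) -> str:
        return "".join(f"{k} = {v}\n" for k, v in asdict(self).items())

    @classmethod
    def from_text(cls, text: str) -> "PipelineConfig":
        known = {f.name: f.type for f in fields(cls)}
        kwargs = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            key = key.strip()
            if key not in known:
                raise ValueError(f"unknown configuration key {key!r}")
            default = getattr(cls, key)
            kwargs[key] = type(default)(value.strip())
        return cls(**kwargs)

    def digest(self) -> str:
        return hashlib.sha256(self.to_text().encode()).hexdigest()[:12]


def fixture_path(name: str) -> Path:
    """Path to a packaged fixture CSV."""
    return Path(resources.files("hmetex") / "data" / name)


def _read_csv(path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", **kw)


def load_design(path: Optional[Union[str, Path]] = None) -> pd.DataFrame:
    """The 27-run screening CCD (factors only)."""
    return _read_csv(path or fixture_path("table1_design.csv"))


def load_validation_design(path: Optional[Union[str, Path]] = None) -> pd.DataFrame:
    return _read_csv(path or fixture_path("table2_validation_design.csv"))


def load_runs_table(path: Optional[Union[str, Path]] = None,
                    protein_id: str = "SPC Alpha 8") -> list[ExtrusionRun]:
    """Extrusion runs with responses from a responses-table CSV.

    "N/A" structuring indices become missing values; SME logged as 0 is
    flagged as unmeasured (no recordable shear), never treated as zero
    mechanical input.
    """
    df = _read_csv(path or fixture_path("table3_responses.csv"),
                   na_values=["N/A"])
    missing = [c for c in _RUNS_COLUMNS if c not in df.columns]
    if missing or df.empty:
        raise ValueError(f"responses table malformed: missing columns {missing}"
                         if missing else "responses table is empty")
    for col in _RUNS_COLUMNS[1:-1]:
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise ValueError(f"non-numeric values in column {col!r}")
    runs = []
    for _, row in df.iterrows():
        sme = float(row.Y3_SME_Wh_per_kg)
        runs.append(ExtrusionRun(
            run_id=str(row.run_id),
            protein_id=protein_id,
            screw_speed_n=float(row.X1_rpm),
            water_content_Xw=float(row.X2_moisture_pct) / 100.0,
            mass_flow_kg_per_h=float(row.X3_kg_per_h),
            barrel_temperature_C=float(row.X4_barrel_C),
            material_temperature_Tin_C=float(row.Y1_material_C),
            pressure_bar=float(row.Y2_pressure_bar),
            SME_measured_Wh_per_kg=sme,
            SME_unmeasured=sme == 0.0,
            structuring_index=None if pd.isna(row.SI) else float(row.SI),
            texture_label=str(row.texture_label),
        ))
    return runs


def save_runs_table(runs: Sequence[ExtrusionRun], path: Union[str, Path]) -> None:
    rows = []
    for r in runs:
        rows.append({
            "run_id": r.run_id,
            "X1_rpm": r.screw_speed_n,
            "X2_moisture_pct": r.water_content_Xw * 100.0,
            "X3_kg_per_h": r.mass_flow_kg_per_h,
            "X4_barrel_C": r.barrel_temperature_C,
            "Y1_material_C": r.material_temperature_Tin_C,
            "Y2_pressure_bar": r.pressure_bar,
            "Y3_SME_Wh_per_kg": 0.0 if r.SME_unmeasured else r.SME_measured_Wh_per_kg,
            "SI": "N/A" if r.structuring_index is None else r.structuring_index,
            "texture_label": r.texture_label,
        })
    pd.DataFrame(rows, columns=_RUNS_COLUMNS).to_csv(path, index=False)


def load_cp_models(path: Optional[Union[str, Path]] = None) -> dict[str, CpMlrModel]:
    df = _read_csv(path or fixture_path("table5_cp_models.csv"))
    return {
        row.protein: CpMlrModel(
            y0=float(row.y0), a_Xw=float(row.a), b_T=float(row.b),
            r_squared=float(row.r2), standard_error=float(row.se),
        )
        for _, row in df.iterrows()
    }


def load_transitions(path: Optional[Union[str, Path]] = None) -> dict[str, TransitionResult]:
    df = _read_csv(path or fixture_path("table5_transitions.csv"))
    return {
        row.protein: TransitionResult(
            T_onset_C=float(row.Tonset_C), T_m_C=float(row.Tm_C),
            T_end_C=float(row.Tend_C), dH_m_J_per_g=float(row.dHm_J_per_g),
            dH_DSC_J_per_g=float(row.dH_DSC_J_per_g),
        )
        for _, row in df.iterrows()
    }


def load_emh_reference(path: Optional[Union[str, Path]] = None) -> pd.DataFrame:
    return _read_csv(path or fixture_path("table6_emh.csv"))


def load_validation_runs(path: Optional[Union[str, Path]] = None) -> pd.DataFrame:
    """Validation campaign with measured responses and reference TI."""
    return _read_csv(path or fixture_path("table7_validation.csv"))


def load_cp_points(path: Union[str, Path]) -> list[CpPoint]:
    df = _read_csv(path)
    return [CpPoint(float(r.temperature_C), float(r.Xw), float(r.cp_J_per_kgK))
            for _, r in df.iterrows()]


def save_cp_points(points: Sequence[CpPoint], path: Union[str, Path]) -> None:
    pd.DataFrame(
        {"Xw": [p.water_mass_fraction for p in points],
         "temperature_C": [p.temperature_C for p in points],
         "cp_J_per_kgK": [p.cp_J_per_kgK for p in points]}
    ).to_csv(path, index=False)


def save_thermogram(tg: Thermogram, path: Union[str, Path]) -> None:
    """Thermogram CSV with metadata in '#' key-value header lines."""
    header = (f"# heating_rate_K_per_min = {tg.heating_rate_K_per_min}\n"
              f"# sample_mass_g = {tg.sample_mass_g}\n"
              f"# water_mass_fraction = {tg.water_mass_fraction}\n")
    body = pd.DataFrame({"temperature_C": tg.temperature_C,
                         "heat_flow_W_per_g": tg.specific_heat_flow_W_per_g})
    with open(path, "w") as fh:
        fh.write(header)
        body.to_csv(fh, index=False)


def load_thermogram(path: Union[str, Path]) -> Thermogram:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line.lstrip("# ").partition("=")
            meta[key.strip()] = float(value)
    df = _read_csv(path)
    return Thermogram(
        df["temperature_C"].to_numpy(),
        df["heat_flow_W_per_g"].to_numpy(),
        heating_rate_K_per_min=meta["heating_rate_K_per_min"],
        sample_mass_g=meta.get("sample_mass_g", 1.0),
        water_mass_fraction=meta.get("water_mass_fraction", 0.6),
    )


def run_full_pipeline(
    config: PipelineConfig,
    runs: pd.DataFrame,
    transitions: dict[str, TransitionResult],
    cp_models: dict[str, CpMlrModel],
) -> pd.DataFrame:
    """Per-run texturization assessment plus per-protein melting hurdle.

    ``runs`` must carry ``protein``, ``run_id``, ``X2_moisture_pct`` and
    ``Tin_C`` columns (the validation-campaign schema).  Returns one row
    per run with TI, predicted class and the protein's EMH temperature.
    An empty runs table yields an empty report.
    """
    logger.info("pipeline config digest=%s seed=%d", config.digest(), config.seed)
    records = []
    emh_cache: dict[str, float] = {}
    for _, row in runs.iterrows():
        protein = row["protein"]
        if protein not in transitions or protein not in cp_models:
            raise KeyError(f"no thermophysical data for protein {protein!r}")
        xw = float(row["X2_moisture_pct"]) / 100.0
        a = assess_run(cp_models[protein], xw, transitions[protein],
                       Tin_C=float(row["Tin_C"]), T0_C=config.T0_feed_C,
                       convention=config.convention,
                       protein_id=protein, run_id=str(row["run_id"]))
        if protein not in emh_cache:
            emh_cache[protein] = minimum_texturization_temperature(
                cp_models[protein], xw, transitions[protein],
                T0_C=config.T0_feed_C, TI_target=config.TI_target,
                convention=config.convention,
            )
        records.append({
            "protein": protein,
            "run_id": str(row["run_id"]),
            "Tin_C": float(row["Tin_C"]),
            "TI": a.TI,
            "TI_rounded": round(a.TI, config.rounding_decimals),
            "predicted_class": classify_ti(a.TI, config.rounding_decimals),
            "EMH_C": emh_cache[protein],
        })
    cols = ["protein", "run_id", "Tin_C", "TI", "TI_rounded",
            "predicted_class", "EMH_C"]
    return pd.DataFrame(records, columns=cols)
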