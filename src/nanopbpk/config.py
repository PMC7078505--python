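"""Run configuration: closed YAML/JSON schema and result serialization.

The schema mirrors the shipped reference parameter table; every field has a
default traceable to that table, unknown keys are rejected, and a fully
resolved configuration is deterministic. Results round-trip through tidy CSV
plus a JSON sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .core import (
    OutputAggregates,
    SimulationConfig,
    SimulationResult,
    aggregate_outputs,
)
from .physiology import BodySpec, TumorSpec, default_body, default_tumor
from .transport import NanoparticleSpec

__all__ = [
    "RunConfig",
    "load_config",
    "write_results",
    "read_results",
    "write_aggregates",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class NanoparticleConfig(_Strict):
    """NP design parameters; ``size_nm`` is the hydrodynamic diameter."""

    size_nm: float = 100.0
    density_g_cm3: float = 2.0
    k_deg_per_h: float = 0.01

    def to_spec(self) -> NanoparticleSpec:
        return NanoparticleSpec.from_diameter(
            self.size_nm, self.density_g_cm3, self.k_deg_per_h
        )


class OrganOverride(_Strict):
    f_wt: Optional[float] = None
    f_v: Optional[float] = None
    f_co: Optional[float] = None
    r_pore_nm: Optional[float] = None


class BodyConfig(_Strict):
    body_weight_g: Optional[float] = None
    cardiac_output_ml_h: Optional[float] = None
    gfr_ml_h: Optional[float] = None
    urine_flow_ml_h: Optional[float] = None
    bile_flow_ml_h: Optional[float] = None
    hematocrit: Optional[float] = None
    lymph_to_plasma_ratio: Optional[float] = None
    plasma_weight_fraction: Optional[float] = None
    lymph_node_volume_fraction: Optional[float] = None
    blood_viscosity_cP: Optional[float] = None
    a_mac_liver: Optional[float] = None
    a_mac_spleen: Optional[float] = None
    organs: Dict[str, OrganOverride] = Field(default_factory=dict)

    def to_spec(self) -> BodySpec:
        over: dict = {"body": {}, "blood": {}, "phagocyte": {}, "organs": {}}
        body_keys = (
            "body_weight_g", "cardiac_output_ml_h", "gfr_ml_h", "urine_flow_ml_h",
            "bile_flow_ml_h", "hematocrit", "lymph_to_plasma_ratio",
            "plasma_weight_fraction", "lymph_node_volume_fraction",
        )
        for k in body_keys:
            v = getattr(self, k)
            if v is not None:
                over["body"][k] = v
        if self.blood_viscosity_cP is not None:
            over["blood"]["viscosity_cP"] = self.blood_viscosity_cP
        if self.a_mac_liver is not None:
            over["phagocyte"]["area_fraction_liver"] = self.a_mac_liver
        if self.a_mac_spleen is not None:
            over["phagocyte"]["area_fraction_spleen"] = self.a_mac_spleen
        for name, org in self.organs.items():
            over["organs"][name] = {
                k: v for k, v in org.model_dump().items() if v is not None
            }
        return default_body(over)


class TumorConfig(_Strict):
    enabled: bool = False
    radius_mm: float = 5.0
    specific_blood_flow_ml_g_min: float = 0.1
    viscosity_cP: float = 7.42
    vascular_fraction: float = 0.1
    pore_radius_nm: float = 850.0
    porosity: float = 0.001
    wall_thickness_um: float = 5.0

    def to_spec(self) -> Optional[TumorSpec]:
        if not self.enabled:
            return None
        return TumorSpec(
            radius_mm=self.radius_mm,
            specific_blood_flow_ml_g_min=self.specific_blood_flow_ml_g_min,
            viscosity_cP=self.viscosity_cP,
            vascular_fraction=self.vascular_fraction,
            pore_radius_nm=self.pore_radius_nm,
            porosity=self.porosity,
            wall_thickness_um=self.wall_thickness_um,
        )


class SimulationSection(_Strict):
    dose_percent_id: float = 100.0
    t_end_h: float = 1000.0
    rtol: float = 1e-8
    atol: float = 1e-10

    def to_spec(self) -> SimulationConfig:
        return SimulationConfig(
            dose_percent_id=self.dose_percent_id, t_end_h=self.t_end_h,
            rtol=self.rtol, atol=self.atol,
        )


class SensitivitySection(_Strict):
    n_samples: int = 5000
    replicates: int = 10
    n_levels: int = 1000
    n_bins: int = 4


class RunConfig(_Strict):
    """Fully resolved run configuration (closed schema)."""

    nanoparticle: NanoparticleConfig = Field(default_factory=NanoparticleConfig)
    body: BodyConfig = Field(default_factory=BodyConfig)
    tumor: TumorConfig = Field(default_factory=TumorConfig)
    simulation: SimulationSection = Field(default_factory=SimulationSection)
    sensitivity: SensitivitySection = Field(default_factory=SensitivitySection)
    seed: int = 0


def load_config(path) -> RunConfig:
    """Parse and validate a YAML or JSON run configuration."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    return RunConfig.model_validate(data)


# ---------------------------------------------------------------------------
# serialization

def result_frame(result: SimulationResult) -> pd.DataFrame:
    """Tidy trajectory table: time_h, compartment, subcompartment, percent_id."""
    rows = []
    for j, name in enumerate(result.index.names):
        comp, _, sub = name.partition(":")
        sub = sub or "total"
        for t, a in zip(result.time_h, result.amounts[:, j]):
            rows.append((t, comp, sub, a))
    df = pd.DataFrame(rows, columns=["time_h", "compartment", "subcompartment",
                                     "percent_id"])
    return df.sort_values(["time_h", "compartment", "subcompartment"],
                          kind="stable").reset_index(drop=True)


def write_results(result: SimulationResult, csv_path, json_path=None) -> None:
    """Write the tidy trajectory CSV and a JSON sidecar of aggregates.

    Full float precision is kept so a read-back reproduces trajectories
    exactly.
    """
    df = result_frame(result)
    df.to_csv(csv_path, index=False)  # default formatting round-trips exactly
    if json_path is not None:
        write_aggregates(aggregate_outputs(result), json_path, result)


def write_aggregates(agg: OutputAggregates, path,
                     result: Optional[SimulationResult] = None) -> None:
    payload = {
        "auc_plasma": agg.auc_plasma,
        "auc_mps": agg.auc_mps,
        "auc_tumor": agg.auc_tumor,
        "auc_excreta": agg.auc_excreta,
        "per_compartment_auc": agg.per_compartment,
        "delivery_efficiency_percent_id": agg.delivery_efficiency_percent_id,
    }
    if result is not None:
        payload["diagnostics"] = {
            "max_conservation_error_percent_id": result.max_conservation_error,
            "solver_status": result.solver_status,
            "n_time_points": int(result.time_h.size),
        }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_results(csv_path) -> pd.DataFrame:
    # round_trip parser: read-back equals what was written, bit for bit
    return pd.read_csv(csv_path, float_precision="round_trip")
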