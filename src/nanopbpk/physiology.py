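"""Whole-body physiology: organ tables, flows, tumor geometry, assembly.

The reference physiology is a 200 g rat. Organ volumes derive from fractional
body weights at unit tissue density; plasma flows from fractional cardiac
output with hepatic portal routing (GI and spleen drain through the liver);
lymph flows are 1/500 of plasma flows. The facultative tumor is a perfused
sphere whose microvascular surface area and capillary hemodynamics are
derived from its vascular fraction and specific blood flow.

Defaults ship in ``nanopbpk/data/parameters.yaml`` and every field can be
overridden.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Dict, List, Optional

import yaml

from .transport import (
    BloodEnvironment,
    CapillaryGeometry,
    InvalidParameterError,
    NanoparticleSpec,
    PhagocyteSpec,
    PhysicalConstants,
    PoreGeometry,
    TransportRateSet,
    compute_transport_rates,
)

__all__ = [
    "OrganSpec",
    "BodySpec",
    "TumorSpec",
    "TumorGeometry",
    "CompartmentEntry",
    "CompartmentParameterization",
    "ORGAN_NAMES",
    "MPS_ORGANS",
    "PORTAL_ORGANS",
    "default_parameter_table",
    "default_body",
    "default_tumor",
    "organ_volumes",
    "organ_flows",
    "tumor_geometry",
    "tumor_capillary_hemodynamics",
    "assemble_parameterization",
]

#: canonical organ ordering (plasma and lymph node are separate pools)
ORGAN_NAMES: tuple = (
    "lungs", "liver", "kidneys", "spleen", "brain", "heart", "gi", "muscle", "others",
)
#: organs with a phagocytic (macrophage) sub-compartment
MPS_ORGANS = ("liver", "spleen")
#: organs whose venous outflow routes through the liver (portal vein)
PORTAL_ORGANS = ("gi", "spleen")


class ConfigurationError(ValueError):
    """Missing or inconsistent physiological configuration."""


def default_parameter_table() -> dict:
    """Load the shipped reference parameter table (deep copy per call)."""
    text = resources.files("nanopbpk.data").joinpath("parameters.yaml").read_text()
    return yaml.safe_load(text)


@dataclass(frozen=True)
class OrganSpec:
    name: str
    f_wt: float          # fractional body weight
    f_v: float           # vascular fraction of the organ
    f_co: float          # fractional cardiac output (liver: hepatic artery only)
    r_pore_nm: float     # vessel-wall fenestration radius
    a_mac: float = 0.0   # macrophage area fraction (MPS organs only)
    viscosity_cP: float = 4.0
    cap: CapillaryGeometry = field(default_factory=CapillaryGeometry)

    def __post_init__(self) -> None:
        for f in (self.f_wt, self.f_v, self.a_mac):
            if not 0.0 <= f <= 1.0:
                raise ConfigurationError(f"{self.name}: fraction out of [0,1]")
        if self.a_mac > 0 and self.name not in MPS_ORGANS:
            raise ConfigurationError(
                f"{self.name}: phagocytic coverage is restricted to MPS organs"
            )


@dataclass(frozen=True)
class BodySpec:
    body_weight_g: float = 200.0
    cardiac_output_ml_h: float = 4217.0
    gfr_ml_h: float = 78.6
    urine_flow_ml_h: float = 2.0833
    bile_flow_ml_h: float = 0.9375
    hematocrit: float = 0.45
    lymph_to_plasma_ratio: float = 1.0 / 500.0
    plasma_weight_fraction: float = 0.0589
    lymph_node_volume_fraction: float = 0.002
    rbc_radius_um: float = 3.6
    organs: tuple = ()

    def __post_init__(self) -> None:
        if self.body_weight_g <= 0:
            raise ConfigurationError("body weight must be > 0")
        if not 0.0 <= self.hematocrit < 1.0:
            raise ConfigurationError("hematocrit must be in [0, 1)")

    def organ(self, name: str) -> OrganSpec:
        for o in self.organs:
            if o.name == name:
                return o
        raise ConfigurationError(f"no organ named {name!r} in body specification")

    @property
    def plasma_volume_ml(self) -> float:
        return self.plasma_weight_fraction * self.body_weight_g

    @property
    def lymph_node_volume_ml(self) -> float:
        return self.lymph_node_volume_fraction * self.body_weight_g


@dataclass(frozen=True)
class TumorSpec:
    radius_mm: float = 5.0
    specific_blood_flow_ml_g_min: float = 0.1
    viscosity_cP: float = 7.42
    vascular_fraction: float = 0.1
    pore_radius_nm: float = 850.0
    porosity: float = 0.001
    wall_thickness_um: float = 5.0

    def __post_init__(self) -> None:
        for name in ("radius_mm", "specific_blood_flow_ml_g_min", "viscosity_cP",
                     "pore_radius_nm", "wall_thickness_um"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"tumor {name} must be > 0")
        if not 0.0 <= self.vascular_fraction <= 1.0:
            raise ConfigurationError("tumor vascular fraction must be in [0,1]")
        if not 0.0 <= self.porosity <= 1.0:
            raise ConfigurationError("tumor porosity must be in [0,1]")


def default_body(overrides: Optional[dict] = None) -> BodySpec:
    """Build the reference body from the shipped table (plus overrides).

    ``overrides`` follows the YAML schema: top-level keys ``body``, ``blood``,
    ``capillary``, ``phagocyte``, ``organs`` (each organ a partial mapping).
    """
    table = default_parameter_table()
    if overrides:
        _deep_update(table, overrides)
    b, bl, cp, ph = table["body"], table["blood"], table["capillary"], table["phagocyte"]
    cap = CapillaryGeometry(
        radius_um=cp["radius_um"], length_um=cp["length_um"],
        glycocalyx_nm=cp["glycocalyx_nm"], velocity_um_s=cp["velocity_um_s"],
        shear_rate_per_s=cp["shear_rate_per_s"],
        capillary_fraction=cp["capillary_fraction"],
    )
    organs = []
    for name in ORGAN_NAMES:
        o = table["organs"][name]
        a_mac = {"liver": ph["area_fraction_liver"],
                 "spleen": ph["area_fraction_spleen"]}.get(name, 0.0)
        organs.append(OrganSpec(
            name=name, f_wt=o["f_wt"], f_v=o["f_v"], f_co=o["f_co"],
            r_pore_nm=o["r_pore_nm"], a_mac=a_mac,
            viscosity_cP=bl["viscosity_cP"], cap=cap,
        ))
    return BodySpec(
        body_weight_g=b["body_weight_g"],
        cardiac_output_ml_h=b["cardiac_output_ml_h"],
        gfr_ml_h=b["gfr_ml_h"],
        urine_flow_ml_h=b["urine_flow_ml_h"],
        bile_flow_ml_h=b["bile_flow_ml_h"],
        hematocrit=b["hematocrit"],
        lymph_to_plasma_ratio=b["lymph_to_plasma_ratio"],
        plasma_weight_fraction=b["plasma_weight_fraction"],
        lymph_node_volume_fraction=b["lymph_node_volume_fraction"],
        rbc_radius_um=bl["rbc_radius_um"],
        organs=tuple(organs),
    )


def default_tumor(overrides: Optional[dict] = None) -> TumorSpec:
    table = default_parameter_table()
    if overrides:
        _deep_update(table, {"tumor": overrides} if "tumor" not in overrides else overrides)
    t = table["tumor"]
    return TumorSpec(
        radius_mm=t["radius_mm"],
        specific_blood_flow_ml_g_min=t["specific_blood_flow_ml_g_min"],
        viscosity_cP=t["viscosity_cP"],
        vascular_fraction=t["vascular_fraction"],
        pore_radius_nm=t["pore_radius_nm"],
        porosity=t["porosity"],
        wall_thickness_um=t["wall_thickness_um"],
    )


def _deep_update(base: dict, overrides: dict) -> dict:
    for k, v in overrides.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v
    return base


# ---------------------------------------------------------------------------
# derived quantities

def organ_volumes(body: BodySpec) -> Dict[str, tuple]:
    """Per-organ (V_total, V_v, V_e) in ml, at unit tissue density."""
    out = {}
    for o in body.organs:
        v_total = o.f_wt * body.body_weight_g
        v_v = o.f_v * v_total
        out[o.name] = (v_total, v_v, v_total - v_v)
    return out


def organ_flows(body: BodySpec) -> Dict[str, tuple]:
    """Per-organ plasma inflow Q and lymph flow L (ml·h⁻¹).

    The lungs carry the full cardiac output in series; the other organs are
    perfused in parallel from the arterial (post-lung) side. The liver's
    inflow is the hepatic-artery share plus the venous outflow of the portal
    organs (GI and spleen), each already diminished by its lymph drainage.
    """
    co = body.cardiac_output_ml_h
    lam = body.lymph_to_plasma_ratio
    parallel_sum = sum(o.f_co for o in body.organs if o.name != "lungs")
    if parallel_sum > 1.0 + 1e-12:
        raise ConfigurationError(
            f"parallel fractional cardiac outputs sum to {parallel_sum} > 1"
        )
    q: Dict[str, float] = {}
    for o in body.organs:
        q[o.name] = (co if o.name == "lungs" else o.f_co * co)
    # portal routing: GI and spleen venous outflow feeds the liver
    q_portal = sum(q[n] * (1.0 - lam) for n in PORTAL_ORGANS)
    q["liver"] = q["liver"] + q_portal
    return {name: (q[name], lam * q[name]) for name in q}


@dataclass(frozen=True)
class TumorGeometry:
    volume_mm3: float
    mass_g: float
    vascular_volume_ml: float
    surface_area_density_mm2_mm3: float
    surface_area_mm2: float
    n_capillaries: float


def tumor_geometry(tumor: TumorSpec, cap: CapillaryGeometry) -> TumorGeometry:
    """Spherical tumor: volume, mass, vascular volume, microvascular surface.

    Surface-area density follows the cylinder lateral-area rule
    s = 2·f_v,T/R for capillaries of radius R; the capillary count partitions
    the capillary share of the vascular volume into single vessels.
    """
    v_t = (4.0 / 3.0) * math.pi * tumor.radius_mm**3          # mm³
    mass = v_t / 1000.0                                        # g at 1 g·cm⁻³
    v_vt = tumor.vascular_fraction * v_t / 1000.0              # ml
    r_mm = cap.radius_um / 1000.0
    l_mm = cap.length_um / 1000.0
    s_density = 2.0 * tumor.vascular_fraction / r_mm           # mm²·mm⁻³
    s_total = s_density * v_t                                  # mm²
    n_cap = cap.capillary_fraction * (v_vt * 1000.0) / (math.pi * r_mm**2 * l_mm)
    return TumorGeometry(v_t, mass, v_vt, s_density, s_total, n_cap)


def tumor_capillary_hemodynamics(tumor: TumorSpec, geom: TumorGeometry) -> CapillaryGeometry:
    """Derive tumor capillary flow, velocity and shear from bulk perfusion.

    Q_T = specific flow × tumor mass is split over the capillary count; the
    mean velocity follows from the lumen cross-section and the shear rate
    from the Poiseuille mean-shear form γ̇ = (8/3)·u/R.
    """
    base = CapillaryGeometry()  # reference geometry (R, l, glycocalyx, f_cap)
    q_total_ml_min = tumor.specific_blood_flow_ml_g_min * geom.mass_g
    q_cap_ml_min = q_total_ml_min / geom.n_capillaries
    q_cap_um3_s = q_cap_ml_min * 1e12 / 60.0                   # ml -> μm³
    u_um_s = q_cap_um3_s / (math.pi * base.radius_um**2)
    shear = (8.0 / 3.0) * u_um_s / base.radius_um
    return CapillaryGeometry(
        radius_um=base.radius_um, length_um=base.length_um,
        glycocalyx_nm=base.glycocalyx_nm, velocity_um_s=u_um_s,
        shear_rate_per_s=shear, capillary_fraction=base.capillary_fraction,
    )


# ---------------------------------------------------------------------------
# assembly

@dataclass(frozen=True)
class CompartmentEntry:
    """Volumes, flows and mechanistic rates for one organ compartment."""

    name: str
    v_total_ml: float
    v_v_ml: float
    v_e_ml: float
    q_ml_h: float            # total plasma inflow
    l_ml_h: float            # lymph flow
    rates: TransportRateSet  # k_on/k_off/k_mac in s⁻¹
    a_mac: float


@dataclass(frozen=True)
class TumorEntry:
    v_v_ml: float
    q_ml_h: float
    surface_area_mm2: float
    ps_ml_h: float
    rates: TransportRateSet
    geometry: TumorGeometry
    capillary: CapillaryGeometry


@dataclass(frozen=True)
class CompartmentParameterization:
    """Complete rate/flow/volume table consumed by the ODE core."""

    nanoparticle: NanoparticleSpec
    body: BodySpec
    organs: Dict[str, CompartmentEntry]
    plasma_volume_ml: float
    lymph_node_volume_ml: float
    cardiac_output_ml_h: float
    gfr_ml_h: float
    urine_flow_ml_h: float
    bile_flow_ml_h: float
    tumor: Optional[TumorEntry] = None

    @property
    def total_lymph_flow_ml_h(self) -> float:
        return sum(e.l_ml_h for e in self.organs.values())


def assemble_parameterization(
    np_spec: NanoparticleSpec,
    body: Optional[BodySpec] = None,
    tumor: Optional[TumorSpec] = None,
    const: PhysicalConstants = PhysicalConstants(),
    phag: Optional[PhagocyteSpec] = None,
) -> CompartmentParameterization:
    """Bind the physiological tables to the mechanistic rate laws.

    Pure function of its inputs: identical inputs give identical tables.
    The tumor entry is present only when a :class:`TumorSpec` is supplied.
    """
    body = body if body is not None else default_body()
    base_phag = phag if phag is not None else PhagocyteSpec()
    volumes = organ_volumes(body)
    flows = organ_flows(body)
    organs: Dict[str, CompartmentEntry] = {}
    for o in body.organs:
        env = BloodEnvironment(
            viscosity_cP=o.viscosity_cP, hematocrit=body.hematocrit,
            rbc_radius_um=body.rbc_radius_um,
        )
        pore = PoreGeometry(pore_radius_nm=o.r_pore_nm)
        ph = replace(base_phag, area_fraction=o.a_mac)
        try:
            rates = compute_transport_rates(np_spec, env, o.cap, pore, ph, const)
        except InvalidParameterError as exc:
            raise InvalidParameterError(f"{o.name}: {exc}") from exc
        v_t, v_v, v_e = volumes[o.name]
        q, l = flows[o.name]
        organs[o.name] = CompartmentEntry(o.name, v_t, v_v, v_e, q, l, rates, o.a_mac)

    tumor_entry = None
    if tumor is not None:
        ref_cap = body.organ("lungs").cap
        geom = tumor_geometry(tumor, ref_cap)
        t_cap = tumor_capillary_hemodynamics(tumor, geom)
        env_t = BloodEnvironment(
            viscosity_cP=tumor.viscosity_cP, hematocrit=body.hematocrit,
            rbc_radius_um=body.rbc_radius_um,
        )
        pore_t = PoreGeometry(
            pore_radius_nm=tumor.pore_radius_nm,
            wall_thickness_um=tumor.wall_thickness_um,
            porosity=tumor.porosity,
        )
        ph0 = replace(base_phag, area_fraction=0.0)  # no phagocytic wall in tumor
        rates_t = compute_transport_rates(
            np_spec, env_t, t_cap, pore_t, ph0, const,
            surface_area_mm2=geom.surface_area_mm2,
        )
        q_t_ml_h = tumor.specific_blood_flow_ml_g_min * geom.mass_g * 60.0
        tumor_entry = TumorEntry(
            v_v_ml=geom.vascular_volume_ml, q_ml_h=q_t_ml_h,
            surface_area_mm2=geom.surface_area_mm2,
            ps_ml_h=rates_t.PS_ml_h, rates=rates_t,
            geometry=geom, capillary=t_cap,
        )

    return CompartmentParameterization(
        nanoparticle=np_spec, body=body, organs=organs,
        plasma_volume_ml=body.plasma_volume_ml,
        lymph_node_volume_ml=body.lymph_node_volume_ml,
        cardiac_output_ml_h=body.cardiac_output_ml_h,
        gfr_ml_h=body.gfr_ml_h, urine_flow_ml_h=body.urine_flow_ml_h,
        bile_flow_ml_h=body.bile_flow_ml_h, tumor=tumor_entry,
    )
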