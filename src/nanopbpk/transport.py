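"""Mechanistic microvascular transport rates for circulating nanoparticles.

The rate constants that couple a nanoparticle (NP) to the microvascular wall
of an organ are derived from first principles rather than fitted:

* ``k_on`` — deposition on the vessel wall, from the Stokes terminal
  sedimentation velocity corrected for advection and (Brownian plus
  shear-induced) diffusion via a Peclet number, then normalised by the
  capillary radius.
* ``k_off`` — dislodging from the glycocalyx, a diffusive escape over the
  glycocalyx thickness.
* ``k_mac`` — phagocytosis by wall-lining macrophages, the inverse of the
  membrane wrapping time set by motor-protein power against membrane tension.
* ``sigma`` — osmotic reflection coefficient of the fenestrated wall, a
  hydrodynamic pore-exclusion function of the NP-to-pore size ratio.
* ``P`` — diffusive permeability of a leaky (tumor) vessel wall through its
  pore network.

All user-facing values carry the units conventional in the PBPK literature
(nm, cP, g·cm⁻³, μm, s⁻¹, mm·s⁻¹); conversion to SI happens internally.
Throughout, NP "size" in user-facing interfaces means hydrodynamic DIAMETER;
the rate laws themselves are written in terms of the radius ``r``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

__all__ = [
    "NanoparticleSpec",
    "PhysicalConstants",
    "BloodEnvironment",
    "CapillaryGeometry",
    "PoreGeometry",
    "PhagocyteSpec",
    "HindranceFactors",
    "TransportRateSet",
    "sedimentation_velocity",
    "brownian_diffusivity",
    "shear_induced_diffusivity",
    "effective_diffusivity",
    "wall_deposition_rate",
    "wall_dislodging_rate",
    "phagocytosis_rate",
    "hindrance_factors",
    "reflection_coefficient",
    "vascular_permeability",
    "compute_transport_rates",
    "renkin_diffusive_hindrance",
    "centerline_convective_hindrance",
    "KMAC_CEILING_PER_S",
]

# unit conversion factors to SI
_NM = 1e-9
_UM = 1e-6
_MM = 1e-3
_CP = 1e-3          # cP -> Pa·s
_G_CM3 = 1e3        # g·cm⁻³ -> kg·m⁻³
_MN_M = 1e-3        # mN·m⁻¹ -> N·m⁻¹

#: default ceiling on the phagocytosis rate (s⁻¹).  The wrapping-time law is
#: unbounded as r -> 0; the cap never binds for r >= 1 nm at default motor
#: power / membrane tension but protects parameter scans.
KMAC_CEILING_PER_S = 1e4


class InvalidParameterError(ValueError):
    """A physical parameter violates its domain (e.g. non-positive radius)."""


@dataclass(frozen=True)
class NanoparticleSpec:
    """The three tunable NP design parameters.

    Parameters
    ----------
    radius_nm : hydrodynamic radius r (nm).
    density_g_cm3 : NP material density ρ_np (g·cm⁻³).
    k_deg_per_h : first-order degradation rate k_deg (h⁻¹) acting on NPs
        sequestered in MPS macrophages or the tumor interstitium.
    """

    radius_nm: float
    density_g_cm3: float = 2.0
    k_deg_per_h: float = 0.01

    def __post_init__(self) -> None:
        if self.radius_nm <= 0:
            raise InvalidParameterError(f"NP radius must be > 0, got {self.radius_nm}")
        if self.density_g_cm3 <= 0:
            raise InvalidParameterError("NP density must be > 0")
        if self.k_deg_per_h < 0:
            raise InvalidParameterError("degradation rate must be >= 0")

    @property
    def diameter_nm(self) -> float:
        """Hydrodynamic diameter 2r — the user-facing "size"."""
        return 2.0 * self.radius_nm

    @classmethod
    def from_diameter(
        cls, diameter_nm: float, density_g_cm3: float = 2.0, k_deg_per_h: float = 0.01
    ) -> "NanoparticleSpec":
        return cls(diameter_nm / 2.0, density_g_cm3, k_deg_per_h)


@dataclass(frozen=True)
class PhysicalConstants:
    k_B: float = 1.38e-23          # Boltzmann constant (J·K⁻¹)
    T: float = 310.0               # body temperature (K)
    g: float = 9.8                 # gravitational acceleration (m·s⁻²)
    rho_plasma_g_cm3: float = 1.0  # plasma density (g·cm⁻³)


@dataclass(frozen=True)
class BloodEnvironment:
    """Rheological state of the blood perfusing one compartment."""

    viscosity_cP: float = 4.0     # dynamic blood viscosity μ
    hematocrit: float = 0.45      # RBC volume fraction H
    rbc_radius_um: float = 3.6    # erythrocyte radius β

    def __post_init__(self) -> None:
        if self.viscosity_cP <= 0:
            raise InvalidParameterError("blood viscosity must be > 0")
        if not 0.0 <= self.hematocrit < 1.0:
            raise InvalidParameterError("hematocrit must be in [0, 1)")
        if self.rbc_radius_um <= 0:
            raise InvalidParameterError("erythrocyte radius must be > 0")


@dataclass(frozen=True)
class CapillaryGeometry:
    """Geometry and hemodynamics of a representative capillary."""

    radius_um: float = 5.0          # R
    length_um: float = 1000.0       # l
    glycocalyx_nm: float = 100.0    # l_g
    velocity_um_s: float = 553.0    # mean blood flow velocity u
    shear_rate_per_s: float = 116.0  # wall shear rate γ̇
    capillary_fraction: float = 0.55  # f_cap, capillary share of vascular volume

    def __post_init__(self) -> None:
        for name in ("radius_um", "length_um", "glycocalyx_nm", "velocity_um_s",
                     "shear_rate_per_s", "capillary_fraction"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")

    @property
    def volumetric_flow_nl_min(self) -> float:
        """Single-capillary flow Q_cap = u·πR² (nl·min⁻¹)."""
        q_m3_s = (self.velocity_um_s * _UM) * math.pi * (self.radius_um * _UM) ** 2
        return q_m3_s * 1e12 * 60.0  # m³·s⁻¹ -> nl·min⁻¹


@dataclass(frozen=True)
class PoreGeometry:
    """Fenestration geometry of a vessel wall.

    ``wall_thickness_um`` and ``porosity`` are only needed for permeability
    (tumor vessels); the reflection coefficient needs only the pore radius.
    """

    pore_radius_nm: float
    wall_thickness_um: Optional[float] = None   # l_w
    porosity: Optional[float] = None            # φ, pore area fraction

    def __post_init__(self) -> None:
        if self.pore_radius_nm <= 0:
            raise InvalidParameterError("pore radius must be > 0")
        if self.porosity is not None and not 0.0 <= self.porosity <= 1.0:
            raise InvalidParameterError("porosity must be in [0, 1]")


@dataclass(frozen=True)
class PhagocyteSpec:
    """Macrophage wrapping machinery and wall coverage."""

    power_W: float = 1e-17            # motor-protein power p
    membrane_tension_mN_m: float = 0.06  # membrane surface tension γ
    macrophage_radius_um: float = 15.0   # r_mac (metadata; coverage is direct input)
    area_fraction: float = 0.0           # A_mac, fraction of wall covered

    def __post_init__(self) -> None:
        if self.power_W <= 0 or self.membrane_tension_mN_m <= 0:
            raise InvalidParameterError("motor power and membrane tension must be > 0")
        if not 0.0 <= self.area_fraction <= 1.0:
            raise InvalidParameterError("macrophage area fraction must be in [0, 1]")


@dataclass(frozen=True)
class HindranceFactors:
    alpha: float
    F: float  # diffusive hindrance
    G: float  # convective hindrance


@dataclass(frozen=True)
class TransportRateSet:
    """Per-compartment mechanistic rates. Rates in s⁻¹, P in mm·s⁻¹."""

    k_on_per_s: float
    k_off_per_s: float
    k_mac_per_s: float
    sigma: float
    P_mm_s: Optional[float] = None
    PS_ml_h: Optional[float] = None


# ---------------------------------------------------------------------------
# hindrance functions

def renkin_diffusive_hindrance(alpha: float) -> float:
    """Centerline diffusive hindrance F(α) for a sphere in a cylindrical pore.

    The classical Renkin polynomial: steric partition (1−α)² times the
    centerline hydrodynamic drag correction.
    """
    if alpha >= 1.0:
        return 0.0
    f = (1.0 - alpha) ** 2 * (
        1.0 - 2.104 * alpha + 2.09 * alpha**3 - 0.95 * alpha**5
    )
    return min(max(f, 0.0), 1.0)


def centerline_convective_hindrance(alpha: float) -> float:
    """Centerline convective lag coefficient G(α) (Anderson–Quinn form)."""
    if alpha >= 1.0:
        return 0.0
    g = (1.0 - (2.0 / 3.0) * alpha**2 - 0.20217 * alpha**5) / (
        1.0 - 0.75857 * alpha**5
    )
    return min(max(g, 0.0), 1.0)


def hindrance_factors(
    alpha: float,
    diffusive: Callable[[float], float] = renkin_diffusive_hindrance,
    convective: Callable[[float], float] = centerline_convective_hindrance,
) -> HindranceFactors:
    """Evaluate the (F, G) pore-hindrance pair at size ratio α = r/r_pore.

    Both factors are clamped to [0, 1] and vanish for α ≥ 1 (NP larger than
    the pore).  Alternative hindrance closures can be plugged in via the
    ``diffusive`` / ``convective`` callables.
    """
    if alpha < 0:
        raise InvalidParameterError("size ratio alpha must be >= 0")
    if alpha >= 1.0:
        return HindranceFactors(alpha, 0.0, 0.0)
    F = min(max(diffusive(alpha), 0.0), 1.0)
    G = min(max(convective(alpha), 0.0), 1.0)
    return HindranceFactors(alpha, F, G)


# ---------------------------------------------------------------------------
# rate laws

def sedimentation_velocity(
    np_spec: NanoparticleSpec,
    env: BloodEnvironment,
    const: PhysicalConstants = PhysicalConstants(),
) -> float:
    """Stokes terminal sedimentation velocity v (m·s⁻¹).

    v = (2/9)·((ρ_np − ρ_p)/μ)·g·r².  Positive for NPs denser than plasma,
    negative for buoyant NPs.
    """
    r = np_spec.radius_nm * _NM
    mu = env.viscosity_cP * _CP
    drho = (np_spec.density_g_cm3 - const.rho_plasma_g_cm3) * _G_CM3
    return (2.0 / 9.0) * (drho / mu) * const.g * r**2


def brownian_diffusivity(
    np_spec: NanoparticleSpec,
    env: BloodEnvironment,
    const: PhysicalConstants = PhysicalConstants(),
) -> float:
    """Stokes–Einstein Brownian diffusivity D_B = k_B·T/(6πμr) (m²·s⁻¹)."""
    r = np_spec.radius_nm * _NM
    mu = env.viscosity_cP * _CP
    return const.k_B * const.T / (6.0 * math.pi * mu * r)


def shear_induced_diffusivity(env: BloodEnvironment, cap: CapillaryGeometry) -> float:
    """Erythrocyte shear-induced diffusivity D_S = 0.3·β²·γ̇·H² (m²·s⁻¹)."""
    beta = env.rbc_radius_um * _UM
    return 0.3 * beta**2 * cap.shear_rate_per_s * env.hematocrit**2


def effective_diffusivity(
    np_spec: NanoparticleSpec,
    env: BloodEnvironment,
    cap: CapillaryGeometry,
    const: PhysicalConstants = PhysicalConstants(),
) -> float:
    """Effective intravascular diffusivity D = D_B + D_S (m²·s⁻¹)."""
    return brownian_diffusivity(np_spec, env, const) + shear_induced_diffusivity(env, cap)


def wall_deposition_rate(
    np_spec: NanoparticleSpec,
    env: BloodEnvironment,
    cap: CapillaryGeometry,
    const: PhysicalConstants = PhysicalConstants(),
) -> float:
    """Wall deposition rate k_on (s⁻¹).

    The sedimentation velocity is divided by the advective Peclet number
    uR²/(D·l) and by the margination length R:

        k_on = v · D·l / (u·R³)

    Buoyant NPs (ρ_np < ρ_p) would give a negative rate; sedimentation-driven
    deposition is one-sided, so the rate is clamped at zero.
    """
    u = cap.velocity_um_s * _UM
    R = cap.radius_um * _UM
    l = cap.length_um * _UM
    if u <= 0:
        raise InvalidParameterError("blood flow velocity must be > 0")
    v = sedimentation_velocity(np_spec, env, const)
    D = effective_diffusivity(np_spec, env, cap, const)
    return max(v * D * l / (u * R**3), 0.0)


def wall_dislodging_rate(
    np_spec: NanoparticleSpec,
    env: BloodEnvironment,
    cap: CapillaryGeometry,
    const: PhysicalConstants = PhysicalConstants(),
) -> float:
    """Dislodging rate k_off = D_B/l_g² (s⁻¹): diffusive escape from the glycocalyx."""
    lg = cap.glycocalyx_nm * _NM
    return brownian_diffusivity(np_spec, env, const) / lg**2


def phagocytosis_rate(
    np_spec: NanoparticleSpec,
    phag: PhagocyteSpec,
    ceiling_per_s: float = KMAC_CEILING_PER_S,
) -> float:
    """Phagocytosis rate k_mac = p/(4πr²γ) (s⁻¹), the inverse wrapping time.

    Diverges as r → 0; clamped at ``ceiling_per_s``.
    """
    r = np_spec.radius_nm * _NM
    gamma = phag.membrane_tension_mN_m * _MN_M
    k = phag.power_W / (4.0 * math.pi * r**2 * gamma)
    return min(k, ceiling_per_s)


def reflection_coefficient(
    np_spec: NanoparticleSpec,
    pore: PoreGeometry,
    diffusive: Callable[[float], float] = renkin_diffusive_hindrance,
    convective: Callable[[float], float] = centerline_convective_hindrance,
) -> float:
    """Osmotic reflection coefficient σ of the fenestrated wall.

    σ = 1 − {[1 − (1 − (1−α)²)²]·G + (16/9)·α²·(1−α)²·F},  α = r/r_pore.

    σ = 0 is free filtration, σ = 1 complete exclusion (α ≥ 1).
    """
    alpha = np_spec.radius_nm / pore.pore_radius_nm
    if alpha >= 1.0:
        return 1.0
    h = hindrance_factors(alpha, diffusive, convective)
    one_m = (1.0 - alpha) ** 2
    w = (1.0 - (1.0 - one_m) ** 2) * h.G + (16.0 / 9.0) * alpha**2 * one_m * h.F
    return min(max(1.0 - w, 0.0), 1.0)


def vascular_permeability(
    np_spec: NanoparticleSpec,
    pore: PoreGeometry,
    env: BloodEnvironment,
    const: PhysicalConstants = PhysicalConstants(),
    diffusive: Callable[[float], float] = renkin_diffusive_hindrance,
) -> float:
    """Diffusive wall permeability P = φ·(1−α)·F(α)·D_B/l_w (mm·s⁻¹).

    ``env`` must carry the viscosity of the blood actually perfusing the leaky
    (tumor) vessels, since D_B is evaluated with it.
    """
    if pore.porosity is None or pore.wall_thickness_um is None:
        raise InvalidParameterError(
            "permeability requires pore porosity and wall thickness"
        )
    alpha = np_spec.radius_nm / pore.pore_radius_nm
    if alpha >= 1.0:
        return 0.0
    D_B = brownian_diffusivity(np_spec, env, const)
    lw = pore.wall_thickness_um * _UM
    F = min(max(diffusive(alpha), 0.0), 1.0)
    P_m_s = pore.porosity * (1.0 - alpha) * F * D_B / lw
    return P_m_s / _MM  # m·s⁻¹ -> mm·s⁻¹


def compute_transport_rates(
    np_spec: NanoparticleSpec,
    env: BloodEnvironment,
    cap: CapillaryGeometry,
    pore: PoreGeometry,
    phag: PhagocyteSpec,
    const: PhysicalConstants = PhysicalConstants(),
    surface_area_mm2: Optional[float] = None,
) -> TransportRateSet:
    """Assemble the full mechanistic rate set for one compartment.

    Permeability (and its surface-area product PS, in ml·h⁻¹) is filled in
    only when the pore geometry carries porosity and wall thickness — i.e.
    for leaky tumor vessels.
    """
    k_on = wall_deposition_rate(np_spec, env, cap, const)
    k_off = wall_dislodging_rate(np_spec, env, cap, const)
    k_mac = phagocytosis_rate(np_spec, phag)
    sigma = reflection_coefficient(np_spec, pore)
    P = PS = None
    if pore.porosity is not None and pore.wall_thickness_um is not None:
        P = vascular_permeability(np_spec, pore, env, const)
        if surface_area_mm2 is not None:
            # mm·s⁻¹ × mm² = mm³·s⁻¹; ×3600/1000 -> ml·h⁻¹
            PS = P * surface_area_mm2 * 3600.0 / 1000.0
    return TransportRateSet(k_on, k_off, k_mac, sigma, P, PS)
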