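"""Hemodynamic state of a vessel segment.

Reynolds number ``Re = rho v D / mu`` classifies the flow regime of each
segment; because Re is linear in diameter at fixed velocity, the main
portal vein (the widest segment) carries the maximal Re.  Vortices appear
already inside the laminar range (Re >~ 40), transition flow spans
2300 < Re < 4000, and Re >= 4000 is persistently turbulent.  Turbulent
eddies drive the tumor particles: the regime maps to the walk's step
acceleration ``m`` through a clamped-linear ramp between vortex onset and
turbulence saturation.

The Womersley number ``alpha = R sqrt(omega rho / mu)`` justifies the
steady-flow, rigid-wall treatment: below 10 the pulsatile component is
damped and the flow is quasi-steady.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "FluidProperties",
    "FlowRegime",
    "HemodynamicState",
    "ParticleForce",
    "HydrostaticState",
    "reynolds_number",
    "classify_regime",
    "womersley_number",
    "step_acceleration",
    "particle_force",
    "hydrostatic_pressure",
    "decompose_velocity",
    "segment_state",
]

#: Vortices arise in laminar pipe flow from roughly this Reynolds number.
RE_VORTEX_ONSET = 40.0
#: Transition flow: 2300 < Re < 4000 (both regime boundaries read literally).
RE_TRANSITION = 2300.0
#: Persistent turbulence: Re >= 4000.
RE_TURBULENT = 4000.0
#: Quasi-steady (Womersley) threshold: alpha < 10.
ALPHA_QUASI_STEADY = 10.0


@dataclass(frozen=True)
class FluidProperties:
    """Bulk blood properties: mass density (kg/m^3) and dynamic viscosity (Pa s)."""

    mass_density: float = 1050.0
    dynamic_viscosity: float = 3.5e-3

    def __post_init__(self) -> None:
        if self.mass_density <= 0 or self.dynamic_viscosity <= 0:
            raise ValueError("fluid density and viscosity must be > 0")


class FlowRegime(enum.Enum):
    LAMINAR_NO_VORTEX = "laminar_no_vortex"
    LAMINAR_VORTEX = "laminar_vortex"
    TRANSITION = "transition"
    TURBULENT = "turbulent"


@dataclass(frozen=True)
class HemodynamicState:
    """Summary of one segment's flow: Re, regime, Womersley, mean/fluctuation split."""

    reynolds: float
    regime: FlowRegime
    womersley: float
    quasi_steady: bool
    mean_velocity: float
    fluctuation_amplitude: float = 0.0


@dataclass(frozen=True)
class ParticleForce:
    """Inputs of the inviscid force balance on one tumor particle.

    ``mass_density_tumor`` is a mass per unit volume (kg/m^3) so that the
    inertial term density * acceleration * volume is a force.
    """

    mass_density_tumor: float
    acceleration: float
    volume: float
    pressure_delta: float
    contact_area: float

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ValueError("particle volume must be > 0")
        if self.contact_area <= 0:
            raise ValueError("particle contact area must be > 0")


@dataclass(frozen=True)
class HydrostaticState:
    """Static balance: pressure force per unit volume vs. gravity potential."""

    pressure_force_per_volume: float
    fluid_density: float
    potential_per_mass: float

    @property
    def residual(self) -> float:
        """-dp - rho*dphi; zero at hydrostatic equilibrium."""
        return (
            -self.pressure_force_per_volume
            - self.fluid_density * self.potential_per_mass
        )


def reynolds_number(props: FluidProperties, velocity: float, diameter: float) -> float:
    """Pipe-flow Reynolds number rho*v*D/mu (all SI: m/s and m)."""
    if velocity < 0:
        raise ValueError("velocity must be >= 0")
    if diameter <= 0:
        raise ValueError("diameter must be > 0")
    return props.mass_density * velocity * diameter / props.dynamic_viscosity


def classify_regime(re: float) -> FlowRegime:
    """Classify Re into the four pipe-flow regimes.

    [0, 40) no vortices; [40, 2300] laminar with vortices; (2300, 4000)
    transition; [4000, inf) turbulent.  Boundary placement follows the
    printed inequalities: 2300 is still laminar, 4000 is turbulent.
    """
    if re < 0:
        raise ValueError("Reynolds number must be >= 0")
    if re < RE_VORTEX_ONSET:
        return FlowRegime.LAMINAR_NO_VORTEX
    if re <= RE_TRANSITION:
        return FlowRegime.LAMINAR_VORTEX
    if re < RE_TURBULENT:
        return FlowRegime.TRANSITION
    return FlowRegime.TURBULENT


def womersley_number(
    radius: float, angular_frequency: float, props: FluidProperties
) -> tuple[float, bool]:
    """Womersley number alpha = R*sqrt(omega*rho/mu) and the quasi-steady flag.

    Quasi-steady iff alpha < 10, strictly: alpha == 10 is not quasi-steady.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    if angular_frequency < 0:
        raise ValueError("angular frequency must be >= 0")
    alpha = radius * math.sqrt(
        angular_frequency * props.mass_density / props.dynamic_viscosity
    )
    return alpha, alpha < ALPHA_QUASI_STEADY


def step_acceleration(
    re: float,
    accel_params: Mapping[str, float] | None = None,
) -> int:
    """Map Reynolds number to the walk's step acceleration ``m``.

    Eddies shorten the walk: the particle reaches the collision site in
    n - m steps.  The map is the model's one invented functional form, a
    clamped-linear ramp

        m = floor(m_max * clamp((Re - re_onset)/(re_saturation - re_onset), 0, 1))

    from vortex onset (default 40) to turbulence saturation (default 4000);
    any monotone non-decreasing map may be substituted by the caller.
    """
    params = dict(accel_params or {})
    m_max = int(params.get("m_max", 5))
    onset = float(params.get("re_onset", RE_VORTEX_ONSET))
    saturation = float(params.get("re_saturation", RE_TURBULENT))
    if re < 0:
        raise ValueError("Reynolds number must be >= 0")
    if m_max < 0:
        raise ValueError("m_max must be >= 0")
    if saturation <= onset:
        raise ValueError("re_saturation must exceed re_onset")
    frac = min(1.0, max(0.0, (re - onset) / (saturation - onset)))
    return int(math.floor(m_max * frac))


def particle_force(pf: ParticleForce) -> float:
    """Inviscid force on one tumor particle: inertia + pressure.

    f_m = M_tumor * a * v_tumor + dP * s_tumor.
    """
    return (
        pf.mass_density_tumor * pf.acceleration * pf.volume
        + pf.pressure_delta * pf.contact_area
    )


def hydrostatic_pressure(fluid_density: float, potential_per_mass: float) -> float:
    """Pressure force per unit volume balancing gravity at rest.

    Returns dp = -rho*dphi so that -dp - rho*dphi = 0 exactly.
    """
    if fluid_density <= 0:
        raise ValueError("fluid density must be > 0")
    return -fluid_density * potential_per_mass


def decompose_velocity(series: Sequence[float]) -> tuple[float, np.ndarray]:
    """Reynolds decomposition of a velocity record into mean + fluctuations.

    The fluctuations sum to zero by construction; reconstruction
    ``mean + fluctuations`` reproduces the input exactly.
    """
    arr = np.asarray(series, dtype=float)
    if arr.size == 0:
        raise ValueError("velocity series must be non-empty")
    mean = float(arr.mean())
    return mean, arr - mean


def segment_state(
    props: FluidProperties,
    velocity: float,
    diameter_m: float,
    *,
    angular_frequency: float = 0.0,
    fluctuation_amplitude: float = 0.0,
) -> HemodynamicState:
    """Convenience: full hemodynamic summary of one segment (SI units)."""
    re = reynolds_number(props, velocity, diameter_m)
    alpha, steady = womersley_number(diameter_m / 2.0, angular_frequency, props)
    return HemodynamicState(
        reynolds=re,
        regime=classify_regime(re),
        womersley=alpha,
        quasi_steady=steady,
        mean_velocity=velocity,
        fluctuation_amplitude=fluctuation_amplitude,
    )
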