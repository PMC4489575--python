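"""Collision probability aggregation and thrombus-site ranking.

A tumor thrombus can only form where the local instantaneous particle
density ``rho_i`` reaches the minimum uniform density ``rho_m`` (density
gate).  Above the gate the expected particle-to-collision-site distance
shrinks with density — here as the 2-D uniform nearest-neighbour scaling
``p = p0 * sqrt(rho_m / rho_i)`` — and the required step count ``i`` is
that distance in unit steps, minus the Reynolds-driven acceleration ``m``.

Aggregating over the sequence of instantaneous cross-section states (the
fourth dimension being time) gives the collision probability

    log p(R4) = sum_m i(m) * log(1/(360 k)) + L * log(1/2)

where ``L`` counts collision points reachable longitudinally from one
direction only.  Segments are ranked by log p(R4); the maximal-probability
segment is the predicted thrombus site.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Callable, Mapping

import pandas as pd

from .hemodynamics import (
    FluidProperties,
    classify_regime,
    reynolds_number,
    step_acceleration,
)
from .vesselgeom import CrossSection, PortalTree, discretize_segment
from .walk import WalkConfig, longitudinal_factor, n_directions

__all__ = [
    "GateStatus",
    "CollisionSite",
    "DensityParams",
    "CrossSectionState",
    "MainVeinState",
    "FourDTrajectory",
    "thrombus_gate",
    "collision_distance",
    "required_steps",
    "site_step_comparison",
    "collision_probability_4d",
    "rank_sites",
    "RANKING_COLUMNS",
]


class GateStatus(enum.Enum):
    NO_THROMBUS = "no_thrombus"
    FEASIBLE = "feasible"


class CollisionSite(enum.Enum):
    MAIN_PORTAL_VEIN = "main_portal_vein"
    OTHER_SITE = "other_site"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class DensityParams:
    """Density calibration: gate threshold rho_m and the reference distance p0.

    ``p0`` is the distance from the walk origin to the collision site when
    the local density equals ``rho_m`` exactly.
    """

    rho_m: float
    p0: float

    def __post_init__(self) -> None:
        if self.rho_m <= 0:
            raise ValueError("rho_m must be > 0")
        if self.p0 <= 0:
            raise ValueError("p0 must be > 0")


@dataclass(frozen=True)
class CrossSectionState:
    """One instantaneous cross-section state contributing to p(R4)."""

    cross_section: CrossSection
    initial_site: tuple[float, float]
    collision_site: tuple[float, float]
    distance: float
    required_steps: int
    reynolds: float
    accel_m: int

    def __post_init__(self) -> None:
        if self.required_steps < 1:
            raise ValueError("required_steps must be >= 1")
        if self.distance < 0:
            raise ValueError("distance must be >= 0")


@dataclass(frozen=True)
class MainVeinState:
    """The main-portal-vein comparator: start site, distance p_m, step count s."""

    start_site: tuple[float, float]
    distance: float
    required_steps: int

    def __post_init__(self) -> None:
        if self.required_steps < 1:
            raise ValueError("required_steps must be >= 1")


@dataclass(frozen=True)
class FourDTrajectory:
    """A sequence of instantaneous 3-D states over time — the 4-D trajectory.

    ``L`` counts collision points along the particle's path where the
    longitudinal collision can occur in only one direction (factor 1/2
    each).
    """

    states: tuple[CrossSectionState, ...]
    L: int = 0

    def __post_init__(self) -> None:
        if not self.states:
            raise ValueError("a 4-D trajectory needs at least one state")
        if self.L < 0:
            raise ValueError("L must be >= 0")

    @property
    def total_steps(self) -> int:
        return sum(s.required_steps for s in self.states)


def thrombus_gate(rho_i: float, rho_m: float) -> GateStatus:
    """Density gate: below rho_m no thrombus can form, whatever the Reynolds number.

    Equality is feasible (the reference case analysed first).
    """
    if rho_i < 0 or rho_m < 0:
        raise ValueError("densities must be >= 0")
    return GateStatus.NO_THROMBUS if rho_i < rho_m else GateStatus.FEASIBLE


def collision_distance(
    rho_i: float,
    params: DensityParams,
    scaling: Callable[[float], float] | None = None,
) -> float:
    """Distance from the walk origin to the collision site at density rho_i.

    Default is the 2-D uniform nearest-neighbour scaling
    ``p = p0 * sqrt(rho_m / rho_i)``: the mean nearest-neighbour distance of
    a planar Poisson point process scales as density^(-1/2).  Any
    monotone-decreasing map of ``rho_i / rho_m`` may be substituted via
    ``scaling`` (called with the density ratio, must return the p/p0
    fraction).  Strictly decreasing in rho_i; p = p0 at rho_i = rho_m.
    """
    if rho_i < params.rho_m:
        raise ValueError(
            "rho_i below rho_m: no thrombus is feasible (see thrombus_gate)"
        )
    ratio = rho_i / params.rho_m
    frac = scaling(ratio) if scaling is not None else 1.0 / math.sqrt(ratio)
    return params.p0 * frac


def required_steps(distance: float, step_length: float, accel_m: int) -> int:
    """Unit steps needed to cover ``distance``, reduced by the acceleration m.

    i = max(1, ceil(distance/step_length) - m); at least one step is always
    required for a collision event.
    """
    if distance < 0:
        raise ValueError("distance must be >= 0")
    if step_length <= 0:
        raise ValueError("step_length must be > 0")
    if accel_m < 0:
        raise ValueError("accel_m must be >= 0")
    return max(1, math.ceil(distance / step_length) - accel_m)


def site_step_comparison(s: int, i: int) -> CollisionSite:
    """Compare the main-vein step count s against a candidate section's i.

    Fewer steps means the likelier collision site: s < i favours the main
    portal vein, s > i the other site; s = i is declared indeterminate.
    """
    if s < 1 or i < 1:
        raise ValueError("step counts must be >= 1")
    if s < i:
        return CollisionSite.MAIN_PORTAL_VEIN
    if s > i:
        return CollisionSite.OTHER_SITE
    return CollisionSite.INDETERMINATE


def collision_probability_4d(traj: FourDTrajectory, k: float) -> float:
    """Log collision probability of a 4-D trajectory.

    log p(R4) = sum_m i(m)*log(1/(360k)) + L*log(1/2), the log of the
    product of per-state fixed-path probabilities times (1/2)^L.
    """
    n_dir = n_directions(k)
    log_step = -math.log(n_dir)
    return traj.total_steps * log_step + longitudinal_factor(traj.L)


RANKING_COLUMNS = [
    "segment_id",
    "name",
    "diameter_mm",
    "Re",
    "regime",
    "gate",
    "i_total",
    "L",
    "log10_p_r4",
    "rank",
    "predicted",
]


def rank_sites(
    tree: PortalTree,
    density_field: Mapping[str, float],
    fluid: FluidProperties,
    walk_config: WalkConfig,
    density_params: DensityParams,
    accel_params: Mapping[str, float] | None = None,
    *,
    n_states_per_segment: int = 1,
    ascending: bool = False,
) -> pd.DataFrame:
    """Score and rank every vessel segment by its collision probability.

    Per segment: Reynolds number from diameter (mm, converted to SI) and
    mean velocity -> step acceleration m -> collision distance from the
    local density -> required steps i per cross-section state ->
    log p(R4) over ``n_states_per_segment`` states, with L accumulated
    from the unidirectional flags along the path from the root.

    Segments whose density fails the gate are listed but excluded from the
    ranking (rank is null, never predicted).  Remaining segments are ranked
    by log p(R4), maximal probability first by default (``ascending=True``
    gives the minimal-p ordering instead); ties break lexicographically by
    segment id.  Returns a DataFrame with columns :data:`RANKING_COLUMNS`.
    """
    if n_states_per_segment < 1:
        raise ValueError("n_states_per_segment must be >= 1")
    missing = [s.id for s in tree.segments if s.id not in density_field]
    if missing:
        raise ValueError(f"density_field missing segments: {missing}")

    rows = []
    for seg in tree.segments:
        rho_i = float(density_field[seg.id])
        gate = thrombus_gate(rho_i, density_params.rho_m)
        diameter_m = seg.diameter * 1e-3
        re = reynolds_number(fluid, seg.mean_velocity, diameter_m)
        regime = classify_regime(re)
        row = {
            "segment_id": seg.id,
            "name": seg.name,
            "diameter_mm": seg.diameter,
            "Re": re,
            "regime": regime.value,
            "gate": gate.value,
            "i_total": None,
            "L": None,
            "log10_p_r4": None,
            "rank": None,
            "predicted": False,
        }
        if gate is GateStatus.FEASIBLE:
            m = step_acceleration(re, accel_params)
            dist = collision_distance(rho_i, density_params)
            slices = discretize_segment(seg, n_states_per_segment, rho_i)
            states = tuple(
                CrossSectionState(
                    cross_section=cs,
                    initial_site=(0.0, 0.0),
                    collision_site=(dist, 0.0),
                    distance=dist,
                    required_steps=required_steps(
                        dist, walk_config.step_length, m
                    ),
                    reynolds=re,
                    accel_m=m,
                )
                for cs in slices
            )
            L = sum(
                1
                for anc in tree.path_to_root(seg.id)
                if anc.longitudinal_unidirectional
            )
            traj = FourDTrajectory(states=states, L=L)
            log_p = collision_probability_4d(traj, walk_config.k)
            row.update(
                i_total=traj.total_steps,
                L=L,
                log10_p_r4=log_p / math.log(10.0),
            )
        rows.append(row)

    table = pd.DataFrame(rows, columns=RANKING_COLUMNS)
    feasible = table["gate"] == GateStatus.FEASIBLE.value
    ranked = table.loc[feasible].sort_values(
        ["log10_p_r4", "segment_id"], ascending=[ascending, True]
    )
    table.loc[ranked.index, "rank"] = range(1, len(ranked) + 1)
    if len(ranked):
        table.loc[ranked.index[0], "predicted"] = True
    order = table["rank"].isna(), table["rank"]
    table = (
        table.assign(_gated=order[0])
        .sort_values(["_gated", "rank", "segment_id"])
        .drop(columns="_gated")
        .reset_index(drop=True)
    )
    return table
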