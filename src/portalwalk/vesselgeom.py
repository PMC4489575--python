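"""Portal venous tree geometry.

The portal tree is modelled as a rooted collection of straight cylindrical
segments (the main portal vein is the root; flow is hepatopetal by default,
toward the liver).  Each segment can be sliced into circular cross-sections
of zero axial extent — the arena on which the in-plane random walk lives —
and carries the local instantaneous tumor-particle density ``rho_i`` per
slice.  Per-cylinder energy-transfer vectors are aggregated by plain vector
superposition; in a healthy tree their sum is parallel to the main-trunk
axis, which fixes the z-axis convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "VesselSegment",
    "PortalTree",
    "CrossSection",
    "EnergyContour",
    "TreeValidationError",
    "build_tree",
    "discretize_segment",
    "contour_energy_sum",
    "set_flow_orientation",
    "tree_to_node_link",
]

#: Flow orientations: hepatopetal = toward the liver (normal), hepatofugal =
#: away from the liver (portal hypertension / cirrhosis).
ORIENTATIONS = ("hepatopetal", "hepatofugal")


class TreeValidationError(ValueError):
    """Raised when a segment set does not form a valid rooted tree."""


@dataclass(frozen=True)
class VesselSegment:
    """One straight cylindrical vessel segment.

    Parameters
    ----------
    id : str
        Unique identifier.
    name : str
        Human-readable label, e.g. ``"main_portal_vein"``.
    diameter : float
        Inner diameter in mm.
    length : float
        Segment length in mm.
    parent : str or None
        Identifier of the upstream segment; ``None`` marks the root
        (the main portal vein).
    longitudinal_unidirectional : bool
        Whether a longitudinal collision at this segment can occur in one
        direction only, contributing a factor 1/2 (rather than 1) to the
        aggregate collision probability.
    mean_velocity : float
        Mean axial blood velocity in m/s.
    """

    id: str
    name: str
    diameter: float
    length: float
    parent: str | None = None
    longitudinal_unidirectional: bool = False
    mean_velocity: float = 0.0

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise TreeValidationError(
                f"segment {self.id!r}: diameter must be > 0, got {self.diameter}"
            )
        if self.length <= 0:
            raise TreeValidationError(
                f"segment {self.id!r}: length must be > 0, got {self.length}"
            )
        if self.mean_velocity < 0:
            raise TreeValidationError(
                f"segment {self.id!r}: mean_velocity must be >= 0"
            )

    @property
    def radius(self) -> float:
        """Cross-section radius in mm."""
        return self.diameter / 2.0


@dataclass(frozen=True)
class PortalTree:
    """A validated rooted tree of :class:`VesselSegment`.

    ``main_axis`` is the unit vector along the main portal vein (the z axis
    by convention).  ``flow_orientation`` controls the sign of longitudinal
    drift in downstream simulation: hepatopetal drift is +1, hepatofugal -1.
    """

    segments: tuple[VesselSegment, ...]
    flow_orientation: str = "hepatopetal"
    main_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        if self.flow_orientation not in ORIENTATIONS:
            raise ValueError(
                f"unknown flow orientation {self.flow_orientation!r}; "
                f"expected one of {ORIENTATIONS}"
            )
        axis = np.asarray(self.main_axis, dtype=float)
        if not np.isclose(np.linalg.norm(axis), 1.0):
            raise ValueError("main_axis must have unit norm")

    def __getitem__(self, segment_id: str) -> VesselSegment:
        for seg in self.segments:
            if seg.id == segment_id:
                return seg
        raise KeyError(segment_id)

    @property
    def root(self) -> VesselSegment:
        return next(s for s in self.segments if s.parent is None)

    @property
    def drift_sign(self) -> int:
        """Sign convention for longitudinal motion (+1 hepatopetal, -1 hepatofugal)."""
        return -1 if self.flow_orientation == "hepatofugal" else +1

    def children(self, segment_id: str) -> tuple[VesselSegment, ...]:
        return tuple(s for s in self.segments if s.parent == segment_id)

    def path_to_root(self, segment_id: str) -> tuple[VesselSegment, ...]:
        """Segments from the root down to ``segment_id`` (inclusive)."""
        chain: list[VesselSegment] = []
        seg = self[segment_id]
        while True:
            chain.append(seg)
            if seg.parent is None:
                break
            seg = self[seg.parent]
        return tuple(reversed(chain))


@dataclass(frozen=True)
class CrossSection:
    """One circular slice of a segment (the zero-length-limit cylinder).

    ``rho_i`` is the local instantaneous tumor-particle density (particles
    per unit area) measured on this slice.
    """

    segment_id: str
    index: int
    radius: float
    axial_position: float
    rho_i: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        if self.rho_i < 0:
            raise ValueError("rho_i must be >= 0")


@dataclass(frozen=True)
class EnergyContour:
    """Per-cylinder energy-transfer vectors sharing one time label.

    The time label tags the instantaneous state (the fourth dimension); it
    is an opaque tag, never a multiplicative factor — the superposition of
    the arrows alone carries the physics.
    """

    time_label: object
    arrows: tuple[tuple[float, float, float], ...] = field(default=())

    def __post_init__(self) -> None:
        if len(self.arrows) < 1:
            raise ValueError("an energy contour needs at least one arrow")


def build_tree(
    segment_descriptors: Sequence[Mapping[str, object]],
    *,
    flow_orientation: str = "hepatopetal",
    main_axis: tuple[float, float, float] = (0.0, 0.0, 1.0),
) -> PortalTree:
    """Assemble and validate a :class:`PortalTree` from field maps.

    Each descriptor needs at least ``id``, ``diameter`` and ``length``;
    ``name`` defaults to the id, ``parent`` to ``None``.  Raises
    :class:`TreeValidationError` naming the offending segment on duplicate
    ids, dangling parents, multiple roots, cycles, or non-positive geometry.
    """
    if not segment_descriptors:
        raise TreeValidationError("no segments given")

    segments: list[VesselSegment] = []
    seen: set[str] = set()
    for desc in segment_descriptors:
        d = dict(desc)
        seg_id = str(d["id"])
        if seg_id in seen:
            raise TreeValidationError(f"duplicate segment id {seg_id!r}")
        seen.add(seg_id)
        segments.append(
            VesselSegment(
                id=seg_id,
                name=str(d.get("name", seg_id)),
                diameter=float(d["diameter"]),
                length=float(d["length"]),
                parent=(None if d.get("parent") in (None, "") else str(d["parent"])),
                longitudinal_unidirectional=bool(
                    d.get("longitudinal_unidirectional", False)
                ),
                mean_velocity=float(d.get("mean_velocity", 0.0)),
            )
        )

    roots = [s for s in segments if s.parent is None]
    if not roots:
        raise TreeValidationError("no root segment (every segment has a parent)")
    if len(roots) > 1:
        ids = ", ".join(repr(s.id) for s in roots)
        raise TreeValidationError(f"multiple roots: {ids}")

    graph = nx.DiGraph()
    graph.add_nodes_from(s.id for s in segments)
    for s in segments:
        if s.parent is not None:
            if s.parent not in seen:
                raise TreeValidationError(
                    f"segment {s.id!r}: missing parent {s.parent!r}"
                )
            graph.add_edge(s.parent, s.id)
    try:
        cycle = nx.find_cycle(graph)
    except nx.NetworkXNoCycle:
        cycle = None
    if cycle:
        members = " -> ".join(edge[0] for edge in cycle)
        raise TreeValidationError(f"cycle in parent links: {members}")
    if not nx.is_arborescence(graph):
        raise TreeValidationError("parent links do not form a rooted tree")

    return PortalTree(
        segments=tuple(segments),
        flow_orientation=flow_orientation,
        main_axis=main_axis,
    )


def discretize_segment(
    segment: VesselSegment,
    n_slices: int,
    density_field: float | Mapping[int, float] | Callable[[float], float],
) -> list[CrossSection]:
    """Slice a segment into ``n_slices`` equally spaced cross-sections.

    Slices are indexed 0-based along the flow direction; ``axial_position``
    is the slice midpoint.  ``density_field`` may be a constant, a mapping
    from slice index to density, or a callable of axial position (mm).
    """
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    spacing = segment.length / n_slices
    out: list[CrossSection] = []
    for i in range(n_slices):
        pos = (i + 0.5) * spacing
        if callable(density_field):
            rho = float(density_field(pos))
        elif isinstance(density_field, Mapping):
            rho = float(density_field[i])
        else:
            rho = float(density_field)
        out.append(
            CrossSection(
                segment_id=segment.id,
                index=i,
                radius=segment.radius,
                axial_position=pos,
                rho_i=rho,
            )
        )
    return out


def contour_energy_sum(
    contour: EnergyContour, *, tolerance: float = 1e-9
) -> tuple[np.ndarray, Callable[[Iterable[float]], bool]]:
    """Superpose a contour's energy arrows.

    Returns the vector sum and a predicate testing whether that sum is a
    non-negative scalar multiple of a query axis (within ``tolerance``).
    A zero sum is parallel to nothing.
    """
    arrows = np.asarray(contour.arrows, dtype=float)
    total = arrows.sum(axis=0)

    def parallel_to(axis: Iterable[float]) -> bool:
        ax = np.asarray(list(axis), dtype=float)
        norm_t = np.linalg.norm(total)
        norm_a = np.linalg.norm(ax)
        if norm_t <= tolerance or norm_a == 0.0:
            return False
        cos = float(np.dot(total, ax) / (norm_t * norm_a))
        return cos >= 1.0 - tolerance

    return total, parallel_to


def set_flow_orientation(tree: PortalTree, orientation: str) -> PortalTree:
    """Return a tree with the given flow orientation; geometry unchanged.

    Hepatofugal flow reverses the sign convention of longitudinal drift in
    downstream simulation (``tree.drift_sign``).  Idempotent.
    """
    if orientation not in ORIENTATIONS:
        raise ValueError(
            f"unknown flow orientation {orientation!r}; expected one of {ORIENTATIONS}"
        )
    return replace(tree, flow_orientation=orientation)


def tree_to_node_link(tree: PortalTree) -> dict:
    """Export the tree as a node-link JSON-ready dict (for plotting)."""
    graph = nx.DiGraph()
    for s in tree.segments:
        graph.add_node(
            s.id,
            name=s.name,
            diameter=s.diameter,
            length=s.length,
            mean_velocity=s.mean_velocity,
        )
    for s in tree.segments:
        if s.parent is not None:
            graph.add_edge(s.parent, s.id)
    return nx.node_link_data(graph, edges="links")
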