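"""Discrete random walk on a circular cross-section.

A tumor particle takes unit steps in one of ``N = 360 k`` equally spaced
directions (each direction spans an arc of ``1/k`` degrees), drawn i.i.d.
and uniformly at each time interval.  The probability of any fixed n-step
direction sequence is ``(1/(360 k))^n``; when turbulent eddies accelerate
the particle it reaches the same site in ``n - m`` steps, whose fixed-path
probability ``(1/(360 k))^(n-m)`` is strictly larger for ``360 k > 1``.

All probabilities are computed and stored in log space: ``(1/360)^n``
underflows double precision near n ~ 120, long before physically relevant
step counts are reached.  The collision event proper — first passage into a
capture disc around a target, or exit through the vessel wall — is measured
by simulation; the closed forms above are fixed-path probabilities, which
is what they literally define.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "WalkConfig",
    "Walk",
    "WalkOutcome",
    "StepGeometry",
    "n_directions",
    "direction_distribution",
    "path_probability",
    "accelerated_path_probability",
    "longitudinal_factor",
    "simulate_walk",
    "step_work",
    "perpendicularity_check",
]


def n_directions(k: float) -> int:
    """Number of walk directions N = 360*k; rejects k with non-integer 360k.

    The direction-resolution parameter k is reciprocal to the arc (in
    degrees) spanned by each direction, so the direction set is well
    defined only when 360*k is an integer >= 2.  Non-conforming k is
    rejected, never rounded.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    n = 360.0 * k
    n_int = round(n)
    if abs(n - n_int) > 1e-9 or n_int < 2:
        raise ValueError(
            f"360*k must be an integer >= 2 (each direction spans 1/k degrees); "
            f"got 360*{k} = {n}"
        )
    return int(n_int)


class WalkOutcome(enum.Enum):
    COLLIDED_PARTICLE = "collided_particle"
    COLLIDED_WALL = "collided_wall"
    NO_COLLISION = "no_collision"


@dataclass(frozen=True)
class WalkConfig:
    """Parameters of the in-plane walk.

    ``step_length`` defaults to one distance unit; ``boundary_radius`` is
    the cross-section radius (wall), ``capture_radius`` the collision
    tolerance around a target particle.
    """

    k: float
    step_length: float = 1.0
    boundary_radius: float = math.inf
    capture_radius: float = 0.5
    max_steps: int = 10_000

    def __post_init__(self) -> None:
        n_directions(self.k)  # validates k
        if self.step_length <= 0:
            raise ValueError("step_length must be > 0")
        if self.capture_radius < 0:
            raise ValueError("capture_radius must be >= 0")
        if self.max_steps < 0:
            raise ValueError("max_steps must be >= 0")

    @property
    def n_dir(self) -> int:
        return n_directions(self.k)


@dataclass(frozen=True)
class Walk:
    """A realized walk: direction indices, positions, and outcome."""

    origin: tuple[float, float]
    steps: tuple[int, ...]
    trajectory: tuple[tuple[float, float], ...]
    outcome: WalkOutcome

    @property
    def n_steps(self) -> int:
        return len(self.steps)


@dataclass(frozen=True)
class StepGeometry:
    """Work bookkeeping for one instantaneous displacement.

    ``ds = dD*sin(theta)`` (theta the angle between the displacement and
    the in-plane curve) and ``dw = F*ds``; both vanish at theta = pi, the
    least-action direction.
    """

    theta: float
    dD: float
    ds: float
    force: float
    dw: float


def direction_distribution(k: float) -> np.ndarray:
    """Uniform probability vector over the N = 360k directions."""
    n = n_directions(k)
    return np.full(n, 1.0 / n)


def path_probability(n: int, k: float) -> float:
    """Log-probability of one fixed n-step direction sequence: n*log(1/(360k))."""
    if n < 0:
        raise ValueError("n must be >= 0")
    n_dir = n_directions(k)
    return -n * math.log(n_dir)


def accelerated_path_probability(n: int, m: int, k: float) -> float:
    """Log-probability of the eddy-accelerated path: (n-m)*log(1/(360k)).

    Requires 0 <= m < n.  For 360k > 1 and m > 0 this strictly exceeds
    :func:`path_probability` — the accelerated, fewer-step path is the more
    probable one.
    """
    if m < 0:
        raise ValueError("m must be >= 0")
    if m >= n:
        raise ValueError("acceleration requires m < n")
    return path_probability(n - m, k)


def longitudinal_factor(L: int) -> float:
    """Log-probability contribution of L unidirectional longitudinal collisions.

    Each such collision point can be reached from one direction only, so it
    contributes a factor 1/2 (bidirectional points contribute 1).
    """
    if L < 0:
        raise ValueError("L must be >= 0")
    return -L * math.log(2.0)


def simulate_walk(
    config: WalkConfig,
    origin: Sequence[float],
    targets: Iterable[Sequence[float]],
    seed: int | np.random.Generator,
) -> Walk:
    """Simulate one walk until particle collision, wall collision, or max_steps.

    Directions are drawn i.i.d. uniformly over the N = 360k angles; each
    step advances by ``step_length``.  The walk terminates on first entry
    into the capture disc of any target (``collided_particle``), on leaving
    the boundary disc (``collided_wall``), or after ``max_steps``
    (``no_collision``).  A fixed integer seed fully determines the walk.
    """
    origin_arr = np.asarray(origin, dtype=float)
    if np.linalg.norm(origin_arr) > config.boundary_radius:
        raise ValueError("origin lies outside the boundary disc")
    target_arr = np.asarray(list(targets), dtype=float).reshape(-1, 2)

    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n_dir = config.n_dir
    angles = 2.0 * np.pi * np.arange(n_dir) / n_dir
    unit = np.column_stack([np.cos(angles), np.sin(angles)])

    pos = origin_arr.copy()
    steps: list[int] = []
    trajectory: list[tuple[float, float]] = [tuple(pos)]
    outcome = WalkOutcome.NO_COLLISION

    def captured(p: np.ndarray) -> bool:
        if target_arr.size == 0:
            return False
        d = np.linalg.norm(target_arr - p, axis=1)
        return bool(np.any(d <= config.capture_radius))

    for _ in range(config.max_steps):
        idx = int(rng.integers(n_dir))
        pos = pos + config.step_length * unit[idx]
        steps.append(idx)
        trajectory.append((float(pos[0]), float(pos[1])))
        if captured(pos):
            outcome = WalkOutcome.COLLIDED_PARTICLE
            break
        if np.linalg.norm(pos) > config.boundary_radius:
            outcome = WalkOutcome.COLLIDED_WALL
            break

    return Walk(
        origin=(float(origin_arr[0]), float(origin_arr[1])),
        steps=tuple(steps),
        trajectory=tuple(trajectory),
        outcome=outcome,
    )


def step_work(theta: float, dD: float, force: float) -> StepGeometry:
    """Work done over one instantaneous displacement: ds = dD*sin(theta), dw = F*ds."""
    if dD < 0:
        raise ValueError("dD must be >= 0")
    ds = dD * math.sin(theta)
    return StepGeometry(theta=theta, dD=dD, ds=ds, force=force, dw=force * ds)


def perpendicularity_check(
    longitudinal: Sequence[float],
    cross_section_tangent: Sequence[float],
    tolerance: float = 1e-9,
) -> bool:
    """Whether longitudinal motion is orthogonal to the in-plane motion curve.

    True iff |cos(angle)| <= tolerance — the least-action condition that the
    along-axis displacement be perpendicular to every possible curve in the
    cross-section.
    """
    u = np.asarray(longitudinal, dtype=float)
    v = np.asarray(cross_section_tangent, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("vectors must be non-zero")
    return bool(abs(float(np.dot(u, v)) / (nu * nv)) <= tolerance)
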