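"""Monte-Carlo oracle for the walk's closed-form probabilities.

Plain (unreduced) Monte Carlo: simulate many independent walks, count
events, report binomial standard errors and z-confidence intervals.  The
oracle validates the fixed-path reading of the path-probability formula —
the only reading the formula supports; first-passage collision rates are
reported as simulation-only quantities with no analytic counterpart
claimed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .walk import Walk, WalkConfig, WalkOutcome, simulate_walk

__all__ = [
    "MCConfig",
    "MCEstimate",
    "KEstimate",
    "estimate_path_probability",
    "estimate_collision_rate",
    "recover_k",
    "compare_analytic_mc",
]


@dataclass(frozen=True)
class MCConfig:
    """Monte-Carlo run parameters: walker count, seed, z for intervals."""

    n_walkers: int
    seed: int = 0
    confidence_z: float = 3.0

    def __post_init__(self) -> None:
        if self.n_walkers < 1:
            raise ValueError("n_walkers must be >= 1")
        if self.confidence_z <= 0:
            raise ValueError("confidence_z must be > 0")


@dataclass(frozen=True)
class MCEstimate:
    """Binomial point estimate with standard error and z-interval."""

    point: float
    stderr: float
    ci_low: float
    ci_high: float
    n: int


@dataclass(frozen=True)
class KEstimate:
    """Recovered direction-resolution parameter with uniformity diagnostics."""

    k_hat: float
    n_dir_observed: int
    p_value: float
    uniform_ok: bool
    n_obs: int


def _binomial_estimate(successes: int, n: int, z: float) -> MCEstimate:
    p = successes / n
    se = math.sqrt(p * (1.0 - p) / n)
    return MCEstimate(
        point=p,
        stderr=se,
        ci_low=max(0.0, p - z * se),
        ci_high=min(1.0, p + z * se),
        n=n,
    )


def estimate_path_probability(
    walk_config: WalkConfig,
    path: Sequence[int],
    mc: MCConfig,
) -> MCEstimate:
    """MC estimate of the probability that a walk's first steps match ``path``.

    Draws ``n_walkers`` independent direction sequences of length
    ``len(path)`` and counts exact matches; reproducible under a fixed
    seed.  The analytic counterpart is ``exp(path_probability(len(path), k))``.
    """
    path_arr = np.asarray(path, dtype=np.int64)
    if path_arr.size == 0:
        raise ValueError("path must have length >= 1")
    n_dir = walk_config.n_dir
    if np.any((path_arr < 0) | (path_arr >= n_dir)):
        raise ValueError(f"path contains direction indices outside [0, {n_dir})")
    rng = np.random.default_rng(mc.seed)
    draws = rng.integers(n_dir, size=(mc.n_walkers, path_arr.size))
    matches = int(np.all(draws == path_arr, axis=1).sum())
    return _binomial_estimate(matches, mc.n_walkers, mc.confidence_z)


def estimate_collision_rate(
    walk_config: WalkConfig,
    origin: Sequence[float],
    targets: Sequence[Sequence[float]],
    mc: MCConfig,
) -> dict[str, MCEstimate]:
    """First-passage outcome frequencies over ``n_walkers`` simulated walks.

    Returns one binomial estimate per outcome (particle, wall, none); the
    three point estimates partition 1.  Requires at least one target or a
    finite boundary, otherwise no collision event is possible.
    """
    if len(targets) == 0 and not math.isfinite(walk_config.boundary_radius):
        raise ValueError("need at least one target or a finite boundary radius")
    rng = np.random.default_rng(mc.seed)
    counts = {o: 0 for o in WalkOutcome}
    for _ in range(mc.n_walkers):
        w: Walk = simulate_walk(walk_config, origin, targets, rng)
        counts[w.outcome] += 1
    return {
        outcome.value: _binomial_estimate(counts[outcome], mc.n_walkers, mc.confidence_z)
        for outcome in WalkOutcome
    }


def recover_k(
    direction_counts: Mapping[int, int] | Sequence[int],
    *,
    alpha: float = 0.01,
) -> KEstimate:
    """Recover k from an observed histogram of direction indices.

    With every direction observed, the support size N gives k = N/360
    directly (also the maximum-likelihood support under the uniform model,
    since any larger support strictly lowers the likelihood of the data).
    A chi-square uniformity test over the observed support reports whether
    the counts are consistent with the uniform walk model; a single
    observed direction with many draws is flagged inconsistent.
    """
    if isinstance(direction_counts, Mapping):
        counts = np.asarray(
            [c for c in direction_counts.values() if c > 0], dtype=float
        )
    else:
        counts = np.asarray([c for c in direction_counts if c > 0], dtype=float)
    total = int(counts.sum())
    if total < 1:
        raise ValueError("empty histogram")
    support = counts.size
    if support < 2:
        # Uniform over >= 2 directions makes repeated single-direction draws
        # vanishingly unlikely; flag rather than estimate.
        return KEstimate(
            k_hat=support / 360.0,
            n_dir_observed=support,
            p_value=0.0,
            uniform_ok=False,
            n_obs=total,
        )
    chi2 = stats.chisquare(counts)
    return KEstimate(
        k_hat=support / 360.0,
        n_dir_observed=support,
        p_value=float(chi2.pvalue),
        uniform_ok=bool(chi2.pvalue > alpha),
        n_obs=total,
    )


def compare_analytic_mc(
    analytic_log_p: float,
    estimate: MCEstimate,
    *,
    confidence_z: float = 3.0,
) -> tuple[bool, float]:
    """Compare a closed-form log-probability against its MC estimate.

    Passes iff |exp(analytic) - point| <= z * stderr; returns the pass flag
    and the z-score (infinite when stderr is zero but the values differ).
    """
    analytic = math.exp(analytic_log_p)
    diff = abs(analytic - estimate.point)
    if estimate.stderr == 0.0:
        return (diff == 0.0), (0.0 if diff == 0.0 else math.inf)
    z = diff / estimate.stderr
    return z <= confidence_z, z
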