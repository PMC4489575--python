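"""Runnable experiments: fixture trees, end-to-end runs, result files.

``generate_fixture_tree`` emulates a 2-3-level portal tree whose main
trunk carries the maximal diameter (and hence the maximal Reynolds
number); ``run_experiment`` composes the density gate, the hemodynamics,
the walk/collision scoring and the Monte-Carlo validation into one
deterministic run; ``write_results`` serializes the run as TSV tables and
a JSON summary.
"""

from __future__ import annotations

import json
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .collision import DensityParams, rank_sites
from .config import ExperimentConfig, subseed
from .hemodynamics import FluidProperties, classify_regime, reynolds_number, womersley_number
from .montecarlo import MCConfig, compare_analytic_mc, estimate_path_probability
from .vesselgeom import PortalTree, build_tree
from .walk import Walk, WalkConfig, path_probability

__all__ = [
    "RunSummary",
    "generate_fixture_tree",
    "fixture_experiment_config",
    "run_experiment",
    "write_results",
    "read_summary",
    "trajectory_frame",
]

# Trunk anatomy of the fixture: a 13 mm main portal vein at 0.26 m/s, which
# puts its Reynolds number near the low end of the reported main-portal range.
_TRUNK_DIAMETER_MM = 13.0
_TRUNK_LENGTH_MM = 60.0
_TRUNK_VELOCITY = 0.26
_CHILD_DIAMETER_RATIO = (0.6, 0.8)


@dataclass
class RunSummary:
    """Everything one experiment produced, timing metadata aside."""

    config: dict
    seed: int
    status: str
    ranking: pd.DataFrame
    mc_validation: pd.DataFrame
    regimes: pd.DataFrame
    wall_clock_s: float = field(default=0.0, compare=False)

    @property
    def predicted_site(self) -> str | None:
        hits = self.ranking.loc[self.ranking["predicted"] == True]  # noqa: E712
        return None if hits.empty else str(hits.iloc[0]["segment_id"])


def generate_fixture_tree(levels: int, seed: int) -> list[dict]:
    """Deterministic binary-branching portal-tree descriptor.

    The trunk (main portal vein) has the strictly maximal diameter; each
    child's diameter is a seeded fraction (0.6-0.8) of its parent's, and
    mean velocity scales with diameter so Re decreases monotonically with
    depth.  Returns descriptors consumable by ``build_tree``.
    """
    if levels < 1:
        raise ValueError("levels must be >= 1")
    rng = np.random.default_rng(seed)
    descriptors = [
        {
            "id": "mpv",
            "name": "main_portal_vein",
            "diameter": _TRUNK_DIAMETER_MM,
            "length": _TRUNK_LENGTH_MM,
            "parent": None,
            "mean_velocity": _TRUNK_VELOCITY,
        }
    ]
    frontier = [descriptors[0]]
    for level in range(1, levels):
        next_frontier = []
        for parent in frontier:
            for side in ("l", "r"):
                ratio = float(rng.uniform(*_CHILD_DIAMETER_RATIO))
                diameter = parent["diameter"] * ratio
                child = {
                    "id": f"{parent['id']}_{side}",
                    "name": f"branch_level{level}_{parent['id']}_{side}",
                    "diameter": diameter,
                    "length": parent["length"] * 0.7,
                    "parent": parent["id"],
                    "mean_velocity": _TRUNK_VELOCITY
                    * diameter
                    / _TRUNK_DIAMETER_MM,
                }
                descriptors.append(child)
                next_frontier.append(child)
        frontier = next_frontier
    return descriptors


def fixture_experiment_config(
    levels: int = 3,
    seed: int = 0,
    *,
    rho_m: float = 1.0,
    p0: float = 6.0,
    uniform_rho: float | None = None,
) -> ExperimentConfig:
    """Ready-to-run config on the fixture tree with uniform density.

    ``uniform_rho`` defaults to ``rho_m`` (every segment exactly at the
    thrombus-formation threshold).
    """
    descriptors = generate_fixture_tree(levels, seed)
    rho = rho_m if uniform_rho is None else uniform_rho
    return ExperimentConfig.model_validate(
        {
            "tree": {"segments": descriptors},
            "density": {
                "rho_m": rho_m,
                "p0": p0,
                "rho_i": {d["id"]: rho for d in descriptors},
            },
            "seed": seed,
        }
    )


def _tree_from_config(config: ExperimentConfig) -> PortalTree:
    return build_tree(
        [s.model_dump() for s in config.tree.segments],
        flow_orientation=config.tree.flow_orientation,
    )


def _regime_table(config: ExperimentConfig, tree: PortalTree) -> pd.DataFrame:
    fluid = FluidProperties(
        config.fluid.mass_density, config.fluid.dynamic_viscosity
    )
    rows = []
    for seg in tree.segments:
        d_m = seg.diameter * 1e-3
        re = reynolds_number(fluid, seg.mean_velocity, d_m)
        alpha, steady = womersley_number(
            d_m / 2.0, config.fluid.angular_frequency, fluid
        )
        rows.append(
            {
                "segment_id": seg.id,
                "name": seg.name,
                "diameter_mm": seg.diameter,
                "mean_velocity": seg.mean_velocity,
                "Re": re,
                "regime": classify_regime(re).value,
                "womersley": alpha,
                "quasi_steady": steady,
            }
        )
    return pd.DataFrame(rows)


def run_experiment(config: ExperimentConfig) -> RunSummary:
    """Gate -> hemodynamics -> walk/collision scoring -> MC validation.

    Deterministic given the config: the global seed is fanned out to the
    Monte-Carlo sub-run via ``subseed(seed, 1)``.  The MC validation
    checks the fixed-path closed form against simulation for a short
    reference path at the configured k.
    """
    t0 = time.perf_counter()
    tree = _tree_from_config(config)
    fluid = FluidProperties(
        config.fluid.mass_density, config.fluid.dynamic_viscosity
    )
    walk_config = WalkConfig(
        k=config.walk.k,
        step_length=config.walk.step_length,
        boundary_radius=config.walk.boundary,
        capture_radius=config.walk.capture_radius,
        max_steps=config.walk.max_steps,
    )
    density_params = DensityParams(rho_m=config.density.rho_m, p0=config.density.p0)
    ranking = rank_sites(
        tree,
        config.density.rho_i,
        fluid,
        walk_config,
        density_params,
        config.accel.model_dump(),
        n_states_per_segment=config.n_states_per_segment,
    )

    regimes = _regime_table(config, tree)

    # MC validation of the fixed-path closed form at this k.  The reference
    # path is as long as the walker budget can resolve (expected match
    # count >= ~50), capped at 3 steps.
    n_dir = walk_config.n_dir
    max_resolvable = math.log(max(config.mc.n_walkers / 50.0, n_dir)) / math.log(n_dir)
    path = [0] * min(3, max(1, int(max_resolvable)))
    mc = MCConfig(
        n_walkers=config.mc.n_walkers,
        seed=subseed(config.seed, 1),
        confidence_z=config.mc.confidence_z,
    )
    est = estimate_path_probability(walk_config, path, mc)
    analytic = path_probability(len(path), walk_config.k)
    ok, z = compare_analytic_mc(analytic, est, confidence_z=mc.confidence_z)
    mc_validation = pd.DataFrame(
        [
            {
                "check": "fixed_path_probability",
                "k": walk_config.k,
                "path_length": len(path),
                "analytic_p": float(np.exp(analytic)),
                "mc_point": est.point,
                "mc_stderr": est.stderr,
                "z_score": z,
                "n_walkers": est.n,
                "seed": mc.seed,
                "passed": ok,
            }
        ]
    )

    any_feasible = bool((ranking["gate"] == "feasible").any())
    status = "ok" if any_feasible else "no_thrombus"
    return RunSummary(
        config=config.model_dump(),
        seed=config.seed,
        status=status,
        ranking=ranking,
        mc_validation=mc_validation,
        regimes=regimes,
        wall_clock_s=time.perf_counter() - t0,
    )


def _write_tsv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def write_results(summary: RunSummary, output_dir: str | Path) -> list[Path]:
    """Write ranking.tsv, mc_validation.tsv, regimes.tsv and summary.json.

    TSVs keep a stable, documented column order; summary.json round-trips
    through :func:`read_summary` (timing metadata aside).
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = []
    for name, frame in (
        ("ranking.tsv", summary.ranking),
        ("mc_validation.tsv", summary.mc_validation),
        ("regimes.tsv", summary.regimes),
    ):
        _write_tsv(frame, out / name)
        files.append(out / name)
    payload = {
        "config": summary.config,
        "seed": summary.seed,
        "status": summary.status,
        "ranking": summary.ranking.to_dict(orient="list"),
        "mc_validation": summary.mc_validation.to_dict(orient="list"),
        "regimes": summary.regimes.to_dict(orient="list"),
        "wall_clock_s": summary.wall_clock_s,
    }
    (out / "summary.json").write_text(json.dumps(payload, indent=2, default=str))
    files.append(out / "summary.json")
    return files


def read_summary(path: str | Path) -> RunSummary:
    """Read a summary.json back into a RunSummary."""
    payload = json.loads(Path(path).read_text())
    return RunSummary(
        config=payload["config"],
        seed=payload["seed"],
        status=payload["status"],
        ranking=pd.DataFrame(payload["ranking"]),
        mc_validation=pd.DataFrame(payload["mc_validation"]),
        regimes=pd.DataFrame(payload["regimes"]),
        wall_clock_s=payload.get("wall_clock_s", 0.0),
    )


def trajectory_frame(walk: Walk) -> pd.DataFrame:
    """A walk's trajectory as a (step, x, y) table, TSV-ready for plotting."""
    return pd.DataFrame(
        {
            "step": range(len(walk.trajectory)),
            "x": [p[0] for p in walk.trajectory],
            "y": [p[1] for p in walk.trajectory],
        }
    )
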