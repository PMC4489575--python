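"""Experiment configuration: pydantic models, JSON/YAML loading, JSON schema.

A single config file fully determines an experiment: the tree geometry,
the fluid, the walk resolution, the density calibration, the Re->m
acceleration map, and the Monte-Carlo validation settings.  One global
seed is fanned out to sub-seeds with a documented counter scheme (see
:func:`subseed`) so each module's randomness is independently
reproducible.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, Field, model_validator

__all__ = [
    "SegmentConfig",
    "TreeConfig",
    "FluidConfig",
    "WalkSection",
    "DensityConfig",
    "AccelConfig",
    "MCSection",
    "ExperimentConfig",
    "load_config",
    "config_schema",
    "subseed",
]


class SegmentConfig(BaseModel):
    id: str
    name: Optional[str] = None
    diameter: float = Field(gt=0, description="inner diameter, mm")
    length: float = Field(gt=0, description="segment length, mm")
    parent: Optional[str] = None
    longitudinal_unidirectional: bool = False
    mean_velocity: float = Field(ge=0, default=0.0, description="mean velocity, m/s")


class TreeConfig(BaseModel):
    segments: list[SegmentConfig] = Field(min_length=1)
    flow_orientation: Literal["hepatopetal", "hepatofugal"] = "hepatopetal"


class FluidConfig(BaseModel):
    mass_density: float = Field(gt=0, default=1050.0, description="kg/m^3")
    dynamic_viscosity: float = Field(gt=0, default=3.5e-3, description="Pa s")
    angular_frequency: float = Field(
        ge=0, default=7.54, description="pulsation, rad/s (~72 bpm)"
    )


class WalkSection(BaseModel):
    k: float = Field(gt=0, default=1.0)
    step_length: float = Field(gt=0, default=1.0)
    boundary_radius: Optional[float] = Field(
        gt=0, default=None, description="cross-section radius; null = unbounded"
    )
    capture_radius: float = Field(ge=0, default=0.5)
    max_steps: int = Field(ge=0, default=10_000)

    @property
    def boundary(self) -> float:
        return math.inf if self.boundary_radius is None else self.boundary_radius


class DensityConfig(BaseModel):
    rho_m: float = Field(gt=0, description="minimum uniform density for thrombus")
    p0: float = Field(gt=0, description="reference origin-to-site distance, walk units")
    rho_i: dict[str, float] = Field(
        description="local instantaneous density per segment id"
    )


class AccelConfig(BaseModel):
    m_max: int = Field(ge=0, default=5)
    re_onset: float = Field(ge=0, default=40.0)
    re_saturation: float = Field(gt=0, default=4000.0)

    @model_validator(mode="after")
    def _ordered(self) -> "AccelConfig":
        if self.re_saturation <= self.re_onset:
            raise ValueError("re_saturation must exceed re_onset")
        return self


class MCSection(BaseModel):
    n_walkers: int = Field(ge=1, default=20_000)
    confidence_z: float = Field(gt=0, default=3.0)


class ExperimentConfig(BaseModel):
    """Everything needed to run one ranking + validation experiment."""

    tree: TreeConfig
    fluid: FluidConfig = FluidConfig()
    walk: WalkSection = WalkSection()
    density: DensityConfig
    accel: AccelConfig = AccelConfig()
    mc: MCSection = MCSection()
    seed: int = 0
    n_states_per_segment: int = Field(ge=1, default=1)
    output_dir: Optional[str] = None

    @model_validator(mode="after")
    def _density_covers_tree(self) -> "ExperimentConfig":
        ids = {s.id for s in self.tree.segments}
        missing = sorted(ids - set(self.density.rho_i))
        if missing:
            raise ValueError(f"density.rho_i missing segments: {missing}")
        return self


def subseed(seed: int, counter: int) -> int:
    """Derive the counter-th sub-seed from the global seed.

    Uses numpy's SeedSequence on the pair (seed, counter), reduced to a
    31-bit integer; deterministic and collision-resistant across counters.
    """
    return int(np.random.SeedSequence([seed, counter]).generate_state(1)[0] % (2**31))


def load_config(path: str | Path) -> ExperimentConfig:
    """Load and validate an experiment config from a JSON or YAML file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    return ExperimentConfig.model_validate(data)


def config_schema() -> dict:
    """JSON schema of the experiment config (shipped for external validation)."""
    return ExperimentConfig.model_json_schema()
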