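"""Run configuration: YAML schema, validation, defaults, builders.

Defaults mirror the benchmark pulling protocol: ten 2 A segments from
13 to 33 A, spring constant 7.2 kcal/mol/A^2, 300 K, friction 5 1/ps,
2 fs timestep, 100 ps inter-stage relaxation.  Unknown keys are
rejected; every validation failure names the offending field.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .asmd import StagePlan, System
from .dynamics import (
    DistanceCoordinate,
    IdentityCoordinate,
    LangevinParams,
    SteeringProtocol,
    SystemState,
)
from .errors import ConfigurationError
from .potentials import PotentialSpec, make_potential

__all__ = ["RunConfig", "load_config", "build_run"]


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SystemConfig(_Model):
    kind: Literal["free", "harmonic", "double_well", "tilted_double_well", "bead_spring_helix"]
    params: dict = Field(default_factory=dict)
    dimension: int = 1
    initial_positions: Optional[list] = None
    initial_velocities: Optional[list] = None


class SteeringConfig(_Model):
    coordinate: Literal["identity", "distance"] = "identity"
    index: int = 0
    atoms: Optional[tuple[int, int]] = None
    k: float = 7.2
    lambda_start: float = 13.0
    lambda_end: float = 33.0
    velocity: float = 10.0  # A/ns


class LangevinConfig(_Model):
    temperature: float = 300.0
    friction: float = 5.0
    timestep: float = 0.002  # ps
    masses: float = 1.0


class PlanConfig(_Model):
    n_segments: int = 10
    tps: int = Field(default=100, ge=1)
    t_relax: float = Field(default=100.0, ge=0.0)
    record_spacing: float = Field(default=0.1, gt=0.0)


class RunConfig(_Model):
    system: SystemConfig
    mode: Literal["smd", "asmd", "frasmd"]
    steering: SteeringConfig = Field(default_factory=SteeringConfig)
    langevin: LangevinConfig = Field(default_factory=LangevinConfig)
    plan: PlanConfig = Field(default_factory=PlanConfig)
    seed: int = 0
    outdir: Optional[str] = None
    relax_mode: Literal["freeze", "hold_spring"] = "freeze"

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(exclude_none=True), fh, sort_keys=True)

    def content_hash(self) -> str:
        payload = json.dumps(self.model_dump(exclude_none=True), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    """Parse and fully validate a YAML run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:  # carries line info in its message
        raise ConfigurationError(f"YAML parse error in {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config root must be a mapping, got {type(raw).__name__}")
    return validate_config(raw)


def validate_config(raw: dict) -> RunConfig:
    try:
        cfg = RunConfig.model_validate(raw)
    except ValidationError as exc:
        lines = []
        for err in exc.errors():
            loc = ".".join(str(p) for p in err["loc"]) or "<root>"
            lines.append(f"{loc}: {err['msg']}")
        raise ConfigurationError("invalid configuration: " + "; ".join(lines)) from exc
    # cross-field checks the schema cannot express
    _ = _build_plan(cfg)  # raises ConfigurationError on bad segmentation
    _build_potential_spec(cfg)
    return cfg


def _build_potential_spec(cfg: RunConfig) -> PotentialSpec:
    return PotentialSpec(cfg.system.kind, cfg.system.params, cfg.system.dimension)


def _build_plan(cfg: RunConfig) -> StagePlan:
    segments = StagePlan.default_segments(
        cfg.steering.lambda_start, cfg.steering.lambda_end, cfg.plan.n_segments
    )
    return StagePlan(
        segments=tuple(segments),
        tps=cfg.plan.tps,
        t_relax=cfg.plan.t_relax,
        record_spacing=cfg.plan.record_spacing,
    )


def build_run(cfg: RunConfig) -> tuple[System, SteeringProtocol, StagePlan, LangevinParams]:
    """Instantiate all simulation objects described by a validated config."""
    potential = make_potential(_build_potential_spec(cfg))
    if cfg.steering.coordinate == "identity":
        xi = IdentityCoordinate(cfg.steering.index)
    else:
        if cfg.steering.atoms is None:
            raise ConfigurationError("steering.atoms required for a distance coordinate")
        xi = DistanceCoordinate(*cfg.steering.atoms)
    steering = SteeringProtocol(
        xi=xi,
        k=cfg.steering.k,
        lam_start=cfg.steering.lambda_start,
        lam_end=cfg.steering.lambda_end,
        velocity=cfg.steering.velocity,
    )
    plan = _build_plan(cfg)
    params = LangevinParams(
        temperature=cfg.langevin.temperature,
        friction=cfg.langevin.friction,
        timestep=cfg.langevin.timestep,
        masses=cfg.langevin.masses,
    )
    dim = potential.dimension
    if cfg.system.initial_positions is not None:
        x0 = np.asarray(cfg.system.initial_positions, dtype=float)
        if x0.shape != (dim,):
            raise ConfigurationError(
                f"system.initial_positions must have {dim} entries, got {x0.shape}"
            )
    elif cfg.steering.coordinate == "identity":
        x0 = np.zeros(dim)
        x0[cfg.steering.index] = cfg.steering.lambda_start
    else:
        raise ConfigurationError(
            "system.initial_positions is required for distance-coordinate systems"
        )
    if cfg.system.initial_velocities is not None:
        v0 = np.asarray(cfg.system.initial_velocities, dtype=float)
        if v0.shape != (dim,):
            raise ConfigurationError(
                f"system.initial_velocities must have {dim} entries, got {v0.shape}"
            )
    else:
        v0 = np.zeros(dim)
    system = System(potential, SystemState(x0, v0))
    return system, steering, plan, params
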