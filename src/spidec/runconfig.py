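"""YAML run configuration with schema validation.

All quantities are in reduced units (sigma, epsilon, tau). Unknown keys are
rejected; defaults follow the canonical protocol of each engine (dt 0.005
for particle systems and 0.001 for chains, friction 0.1, MC cube side 0.09,
rotation bound 0.05 rad, slice thicknesses 0.1/1.0, H/L cutoffs 0.55/0.25).
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .configuration import (
    HP_SEQUENCE_DEFAULT,
    Box,
    ModelSpec,
)
from .md import MDParams, default_timestep
from .mc import MCParams

__all__ = ["RunConfig", "load_config", "ConfigError"]


class ConfigError(ValueError):
    pass


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ModelSection(_Strict):
    system_kind: str
    epsilon: float = 1.0
    sigma: float = 1.0
    r_cut: float | None = None
    k_spring: float = 75000.0
    chain_length: int = 10
    hp_sequence: str = HP_SEQUENCE_DEFAULT
    cos_theta_s: float = 0.65
    lambda_range: float = 0.5

    def build(self) -> ModelSpec:
        k = self.system_kind
        if k == "lj_particle":
            return ModelSpec.lj_particle(self.epsilon, self.sigma, self.r_cut or 3.0)
        if k == "lj_chain":
            return ModelSpec.lj_chain(
                self.k_spring, self.chain_length, self.epsilon, self.sigma,
                self.r_cut or 6.0,
            )
        if k == "hp_chain":
            return ModelSpec.hp_chain(
                self.hp_sequence, self.k_spring, self.epsilon, self.sigma,
                self.r_cut or 6.0,
            )
        if k == "patchy":
            return ModelSpec.patchy(
                self.epsilon, self.sigma, self.cos_theta_s, self.lambda_range
            )
        raise ConfigError(f"model.system_kind: unknown kind {k!r}")


class GeometrySection(_Strict):
    Lx: float = Field(gt=0)
    Lz_over_Lx: float = Field(default=1.0, ge=1.0)
    rho0: float = Field(gt=0)

    def build_box(self) -> Box:
        return Box.rectangular(self.Lx, self.Lz_over_Lx)


class EngineSection(_Strict):
    kind: str = "md"  # md | mc
    n_steps: int = Field(default=100_000, gt=0)
    temperature: float = Field(gt=0)
    dt: float | None = None
    friction: float = 0.1
    displacement_side: float = 0.09
    rotation_halfwidth: float = 0.05
    save_interval: int = 1000
    pressure_interval: int = 10

    @model_validator(mode="after")
    def _check_kind(self):
        if self.kind not in ("md", "mc"):
            raise ValueError("engine.kind must be 'md' or 'mc'")
        return self


class AnalysisSection(_Strict):
    rho_H: float = 0.55
    rho_L: float = 0.25
    profile_slice: float = 0.1
    slab_slice: float = 1.0
    axis: str | None = None

    @model_validator(mode="after")
    def _check(self):
        if self.rho_H <= self.rho_L:
            raise ValueError("analysis.rho_H must exceed analysis.rho_L")
        if self.axis is not None and self.axis not in ("x", "y", "z"):
            raise ValueError("analysis.axis must be x, y or z")
        return self


class OutputSection(_Strict):
    directory: str = "."
    prefix: str = "run"


class RunConfig(_Strict):
    model: ModelSection
    geometry: GeometrySection
    engine: EngineSection
    analysis: AnalysisSection = AnalysisSection()
    output: OutputSection = OutputSection()
    seed: int = 0

    def build_model(self) -> ModelSpec:
        return self.model.build()

    def build_box(self) -> Box:
        return self.geometry.build_box()

    def build_engine_params(self, model: ModelSpec):
        e = self.engine
        if e.kind == "md":
            return MDParams(
                n_steps=e.n_steps,
                temperature=e.temperature,
                dt=e.dt if e.dt is not None else default_timestep(model),
                friction=e.friction,
                save_interval=e.save_interval,
                pressure_interval=e.pressure_interval,
                seed=self.seed,
            )
        return MCParams(
            n_steps=e.n_steps,
            temperature=e.temperature,
            displacement_side=e.displacement_side,
            rotation_halfwidth=e.rotation_halfwidth,
            save_interval=e.save_interval,
            pressure_interval=e.pressure_interval if model.kind != "patchy" else 0,
            seed=self.seed,
        )


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration; raises ConfigError with
    field-level messages on schema violations."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    try:
        return RunConfig.model_validate(raw)
    except Exception as exc:  # pydantic.ValidationError
        raise ConfigError(f"{Path(path).name}: {exc}") from exc
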