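"""Configuration loading, validation and presets.

Run configurations are YAML or JSON files with ``model``, ``grid``,
``policy`` and ``simulation`` sections; every field is validated (types,
ranges, the m-divisible-by-6 rule) and unknown keys are rejected.  All
defaults equal the nominal parameter set used by the disruption protocol.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .control import StimulationPolicy
from .model import (
    ActivationParams,
    KernelParams,
    NeuralFieldModel,
    build_alpha,
    build_grid,
    build_kernels,
    build_delays,
)
from .simulate import SimConfig

__all__ = ["RunConfig", "load_config", "config_hash", "fixture_configs", "build_from_config"]

SCHEMA_VERSION = 1


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


class GridSection(_Strict):
    m: int = 60
    scale_mm: float = Field(15.0, gt=0)

    @model_validator(mode="after")
    def _check_m(self):
        if self.m < 6 or self.m % 6 != 0:
            raise ValueError(
                f"grid.m must be a positive multiple of 6 (m/6 STN + m/6 GPe + silent); got {self.m}"
            )
        return self


class ModelSection(_Strict):
    tau1: float = Field(6.0, gt=0)
    tau2: float = Field(14.0, gt=0)
    m1: float = Field(300.0, gt=0)
    b1: float = Field(17.0, gt=0)
    m2: float = Field(400.0, gt=0)
    b2: float = Field(75.0, gt=0)
    K12: float = Field(30.0, ge=0)
    K21: float = Field(38.0, ge=0)
    K22: float = Field(2.55, ge=0)
    sigma12: float = Field(0.03, gt=0)
    sigma21: float = Field(0.03, gt=0)
    sigma22: float = Field(0.015, gt=0)
    mu1: float | None = None
    mu2: float | None = None
    c1: float = Field(0.166, gt=0)
    c2: float = Field(0.09, gt=0)
    quadrature: Literal["measure", "plain"] = "measure"
    cortical_rate: float = 27.0
    striatal_rate: float = 2.0
    noise_variance: float = Field(0.05, ge=0)
    cortical_weight: float = 12.5
    striatal_weight: float = 110.0
    striatal_sign: float = -1.0

    @model_validator(mode="after")
    def _check_sigmoids(self):
        if not (0 < self.b1 < self.m1 and 0 < self.b2 < self.m2):
            raise ValueError("sigmoid parameters need 0 < b_i < m_i")
        return self


class PolicySection(_Strict):
    variant: Literal["none", "proportional", "averaged", "delayed_proportional"] = (
        "proportional"
    )
    kc: float = Field(2.0, ge=0)
    zref: float | list[float] = 0.0
    degeneracy: float = Field(0.0, ge=0, le=1)
    mask_seed: int | None = None
    T: float = Field(0.0, ge=0)
    alpha_center_mm: float = 1.25
    alpha_variance_mm2: float = Field(1.25, gt=0)
    averaged_mode: Literal["integral", "mean", "sum"] = "integral"
    stimulation_weight: float = 12.5


class SimulationSection(_Strict):
    dt: float = Field(1.0, gt=0)
    t_f: float = Field(1000.0, gt=0)
    stim_onset: float = Field(500.0, ge=0)
    seed: int | None = None
    initial_history: Literal["zeros", "baseline", "random"] = "zeros"
    noise_shared: bool = False

    @model_validator(mode="after")
    def _check_onset(self):
        if self.stim_onset > self.t_f:
            raise ValueError("simulation.stim_onset must not exceed t_f")
        return self


class RunConfig(_Strict):
    """Validated, hashable run configuration (defaults = nominal protocol B)."""

    schema_version: int = SCHEMA_VERSION
    grid: GridSection = GridSection()
    model: ModelSection = ModelSection()
    policy: PolicySection = PolicySection()
    simulation: SimulationSection = SimulationSection()

    @model_validator(mode="after")
    def _check_euler(self):
        if self.simulation.dt >= min(self.model.tau1, self.model.tau2):
            raise ValueError("simulation.dt must be smaller than both membrane time constants")
        return self

    def canonical_json(self) -> str:
        return json.dumps(self.model_dump(mode="json"), sort_keys=True, separators=(",", ":"))

    @property
    def hash(self) -> str:
        return config_hash(self)


def config_hash(cfg: RunConfig) -> str:
    """SHA-256 over the canonicalized config content (format-independent)."""
    return hashlib.sha256(cfg.canonical_json().encode()).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration.

    An empty file yields the full nominal defaults.  Schema violations raise
    with the offending field path; unknown keys are rejected.
    """
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) if text.strip() else {}
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    return RunConfig(**data)


def build_from_config(cfg: RunConfig) -> tuple[NeuralFieldModel, SimConfig, StimulationPolicy]:
    """Materialize the model, simulation config and policy from a RunConfig."""
    grid = build_grid(cfg.grid.m, cfg.grid.scale_mm)
    kp = KernelParams(
        K12=cfg.model.K12,
        K21=cfg.model.K21,
        K22=cfg.model.K22,
        sigma12=cfg.model.sigma12,
        sigma21=cfg.model.sigma21,
        sigma22=cfg.model.sigma22,
        mu1=cfg.model.mu1,
        mu2=cfg.model.mu2,
    )
    model = NeuralFieldModel(
        grid=grid,
        act1=ActivationParams(cfg.model.m1, cfg.model.b1),
        act2=ActivationParams(cfg.model.m2, cfg.model.b2),
        kernel_params=kp,
        kernels=build_kernels(grid, kp, quadrature=cfg.model.quadrature),
        delays=build_delays(grid, cfg.model.c1, cfg.model.c2, cfg.simulation.dt),
    )
    sim_cfg = SimConfig(
        tau1=cfg.model.tau1,
        tau2=cfg.model.tau2,
        dt=cfg.simulation.dt,
        t_f=cfg.simulation.t_f,
        stim_onset=cfg.simulation.stim_onset,
        cortical_rate=cfg.model.cortical_rate,
        striatal_rate=cfg.model.striatal_rate,
        noise_variance=cfg.model.noise_variance,
        cortical_weight=cfg.model.cortical_weight,
        striatal_weight=cfg.model.striatal_weight,
        striatal_sign=cfg.model.striatal_sign,
        stimulation_weight=cfg.policy.stimulation_weight,
        noise_shared=cfg.simulation.noise_shared,
        initial_history=cfg.simulation.initial_history,
        seed=cfg.simulation.seed,
    )
    alpha = build_alpha(
        grid,
        center_mm=cfg.policy.alpha_center_mm,
        variance_mm2=cfg.policy.alpha_variance_mm2,
        degeneracy=cfg.policy.degeneracy,
        seed=cfg.policy.mask_seed,
    )
    zref = cfg.policy.zref
    policy = StimulationPolicy(
        variant=cfg.policy.variant,
        kc=cfg.policy.kc,
        zref=zref if isinstance(zref, float) else __import__("numpy").asarray(zref, float),
        alpha=alpha,
        T=cfg.policy.T,
        averaged_mode=cfg.policy.averaged_mode,
    )
    return model, sim_cfg, policy


def fixture_configs() -> dict[str, RunConfig]:
    """Named presets reproducing each protocol row, plus a fast "tiny" grid."""
    return {
        "protocol-A": RunConfig(policy=PolicySection(variant="none", kc=0.0)),
        "protocol-B": RunConfig(),
        "protocol-C": RunConfig(policy=PolicySection(degeneracy=0.5, mask_seed=0)),
        "protocol-D": RunConfig(policy=PolicySection(variant="averaged", kc=6.5)),
        "protocol-E": RunConfig(policy=PolicySection(variant="delayed_proportional", T=5.0)),
        "tiny": RunConfig(
            grid=GridSection(m=6),
            simulation=SimulationSection(t_f=200.0, stim_onset=100.0),
        ),
    }
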