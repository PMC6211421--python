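"""End-to-end pipeline configuration with YAML (de)serialization.

All defaults are the study configuration: d=3, tau=1 embedding; 17-nodes-per-
dimension lattice on [-1.2, 1.2]^4 (N = 83521) with width 0.15; observer gains
a=0.5, Gamma=1.5; estimator gain 30 with Tc=1.08 s; 18 ACL-D + 28 ACL-I
synthetic subjects at 60 Hz for 15 s.  Unknown keys are rejected.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import yaml

from gaitdyn.classify import AGGREGATES
from gaitdyn.detlearn import TrainingConfig
from gaitdyn.errors import ConfigError
from gaitdyn.psr import EmbeddingConfig, LagMode
from gaitdyn.simulate import GroupKinematicParams, SimulatorConfig


@dataclass(frozen=True)
class LatticeConfig:
    nodes_per_dim: int = 17
    span: Tuple[float, float] = (-1.2, 1.2)
    width: Optional[float] = None  # None -> grid spacing

    def __post_init__(self) -> None:
        if self.nodes_per_dim < 2:
            raise ConfigError("lattice nodes_per_dim must be >= 2")


@dataclass(frozen=True)
class ClassifierConfig:
    b: float = 30.0
    tc_s: float = 1.08
    aggregate: str = "mean_states"

    def __post_init__(self) -> None:
        if self.b <= 0 or self.tc_s <= 0:
            raise ConfigError("classifier gains must be positive")
        if self.aggregate not in AGGREGATES:
            raise ConfigError(f"aggregate must be one of {AGGREGATES}")


@dataclass(frozen=True)
class EvaluationConfig:
    protocol: str = "loso"  # or "twofold"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.protocol not in ("loso", "twofold"):
            raise ConfigError("protocol must be 'loso' or 'twofold'")


@dataclass(frozen=True)
class PipelineConfig:
    embedding: EmbeddingConfig = field(default_factory=EmbeddingConfig)
    lattice: LatticeConfig = field(default_factory=LatticeConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    simulator: SimulatorConfig = field(default_factory=SimulatorConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {
                    f.name: enc(getattr(obj, f.name))
                    for f in dataclasses.fields(obj)
                }
            if isinstance(obj, LagMode):
                return obj.value
            if isinstance(obj, tuple):
                return list(obj)
            if isinstance(obj, dict):
                return {k: enc(v) for k, v in obj.items()}
            return obj

        return enc(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        return cls(
            embedding=_build(EmbeddingConfig, data.pop("embedding", {}),
                             {"lag_mode": LagMode}),
            lattice=_build(LatticeConfig, data.pop("lattice", {}),
                           tuples=("span",)),
            training=_build(TrainingConfig, data.pop("training", {})),
            classifier=_build(ClassifierConfig, data.pop("classifier", {})),
            simulator=_build_simulator(data.pop("simulator", {})),
            evaluation=_build(EvaluationConfig, data.pop("evaluation", {})),
            **_reject_unknown(cls, data),
        )


def _reject_unknown(cls, leftover: dict) -> dict:
    if leftover:
        raise ConfigError(f"unknown config keys: {sorted(leftover)}")
    return {}


def _build(cls, data: dict, enums: Optional[dict] = None, tuples=()):
    if not isinstance(data, dict):
        raise ConfigError(f"{cls.__name__} section must be a mapping")
    data = dict(data)
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    for key, enum_cls in (enums or {}).items():
        if key in data:
            data[key] = enum_cls(data[key])
    for key in tuples:
        if key in data:
            data[key] = tuple(data[key])
    return cls(**data)


def _build_simulator(data: dict) -> SimulatorConfig:
    data = dict(data)
    for key in ("params_acl_d", "params_acl_i"):
        if key in data and isinstance(data[key], dict):
            data[key] = _build(GroupKinematicParams, data[key])
    return _build(SimulatorConfig, data)


def load_config(path) -> PipelineConfig:
    """Read a pipeline config from YAML (missing sections take defaults)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config file must contain a YAML mapping")
    return PipelineConfig.from_dict(raw)


def save_config(config: PipelineConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
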