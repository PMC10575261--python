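"""Validated run configuration (YAML-backed) and the shipped profiles."""
from __future__ import annotations

import importlib.resources

import yaml
from pydantic import BaseModel, Field, field_validator

from .model import ModelConfig
from .spade import SpadeConfig

__all__ = ["RunConfig", "load_config", "load_profile", "PROFILES"]

PROFILES = ("paper", "desk")


class SpadeSection(BaseModel):
    d_model: int = 256
    window: int = Field(32, ge=0)
    n_heads: int = Field(8, ge=1)
    d_ffn: int = Field(512, ge=1)
    ssm_state_dim: int = Field(64, ge=1)
    n_local_layers: int = Field(1, ge=0)


class ModelSection(BaseModel):
    n_residual_layers: int = Field(4, ge=1)
    residual_channels: int = Field(256, ge=1)
    skip_channels: int = Field(256, ge=1)
    diff_embed_dims: tuple[int, int, int] = (128, 256, 256)
    label_dim: int = Field(12, ge=1)
    signal_channels: int = Field(8, ge=1)
    spade: SpadeSection = SpadeSection()

    def build(self) -> ModelConfig:
        return ModelConfig(
            n_residual_layers=self.n_residual_layers,
            residual_channels=self.residual_channels,
            skip_channels=self.skip_channels,
            diff_embed_dims=tuple(self.diff_embed_dims),
            label_dim=self.label_dim,
            signal_channels=self.signal_channels,
            spade=SpadeConfig(**self.spade.model_dump()))


class ScheduleSection(BaseModel):
    T: int = Field(200, ge=1)
    beta_start: float = Field(1e-4, gt=0, lt=1)
    beta_end: float = Field(0.02, gt=0, lt=1)

    @field_validator("beta_end")
    @classmethod
    def _ordered(cls, v, info):
        if "beta_start" in info.data and v < info.data["beta_start"]:
            raise ValueError("beta_end must be >= beta_start")
        return v


class OptimizerSection(BaseModel):
    name: str = "adam"
    learning_rate: float = Field(2e-4, gt=0)

    @field_validator("name")
    @classmethod
    def _adam_only(cls, v):
        if v.lower() != "adam":
            raise ValueError(f"unsupported optimizer {v!r}")
        return v


class DataSection(BaseModel):
    kind: str = "synthetic"          # "synthetic" | "hdf5" | "wfdb"
    path: str | None = None
    n_records: int = Field(2000, ge=1)
    fs: float = Field(64.0, gt=0)
    duration_s: float = Field(2.0, gt=0)
    n_leads: int = 2
    noise_sd: float = Field(0.05, ge=0)

    @field_validator("kind")
    @classmethod
    def _known_kind(cls, v):
        if v not in ("synthetic", "hdf5", "wfdb"):
            raise ValueError(f"unknown data kind {v!r}")
        return v


class TrainSection(BaseModel):
    steps: int = Field(2000, ge=1)
    batch_size: int = Field(16, ge=1)
    log_every: int = Field(50, ge=0)
    checkpoint_every: int = Field(500, ge=0)


class RunConfig(BaseModel):
    model: ModelSection = ModelSection()
    schedule: ScheduleSection = ScheduleSection()
    optimizer: OptimizerSection = OptimizerSection()
    data: DataSection = DataSection()
    train: TrainSection = TrainSection()
    seed: int = 0
    output_dir: str = "runs/default"


def load_config(path: str) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)


def load_profile(name: str) -> RunConfig:
    if name not in PROFILES:
        raise ValueError(f"unknown profile {name!r}; choose from {PROFILES}")
    text = importlib.resources.files("ecgdiff").joinpath(
        f"profiles/{name}.yaml").read_text()
    return RunConfig.model_validate(yaml.safe_load(text))
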