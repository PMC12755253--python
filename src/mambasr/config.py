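"""Run configuration: YAML round-trip with strict key checking."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .architecture import ModelConfig
from .training_loss import LossConfig, TrainConfig

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config", "config_hash"]


class ConfigError(ValueError):
    """Raised on unknown or malformed configuration keys."""


@dataclass
class RunConfig:
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    loss: LossConfig = field(default_factory=LossConfig)
    preprocess_preset: str = "brain4x"
    data_dir: Optional[str] = None
    out_dir: str = "out"
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key, sub_cls in (("model", ModelConfig), ("train", TrainConfig),
                             ("loss", LossConfig)):
            if key in d and isinstance(d[key], dict):
                sub_known = {f.name for f in dataclasses.fields(sub_cls)}
                sub_unknown = set(d[key]) - sub_known
                if sub_unknown:
                    raise ConfigError(f"unknown {key} config keys: {sorted(sub_unknown)}")
                try:
                    d[key] = sub_cls(**d[key])
                except (TypeError, ValueError) as exc:
                    raise ConfigError(f"invalid {key} config: {exc}") from exc
        return cls(**d)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as f:
        raw = yaml.safe_load(f)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a YAML mapping")
    return RunConfig.from_dict(raw)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as f:
        yaml.safe_dump(cfg.to_dict(), f, sort_keys=True)


def config_hash(cfg: RunConfig) -> str:
    """Stable digest of the full configuration, for run provenance."""
    payload = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:12]
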