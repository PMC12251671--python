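"""Nested run configuration with lossless YAML round-tripping.

One :class:`RunConfig` carries every tunable of a workflow (synthesis,
model, training, anthropometry, evaluation) plus the seed and output
directory; its hash is stamped into every artifact a command writes so
results remain traceable to their exact configuration.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .losses import LossWeights
from .network import ModelConfig, TrainConfig, desk_model_config, \
    desk_train_config
from .synth import SynthConfig

__all__ = ["RunConfig", "load_config", "save_config"]

_TUPLE_FIELDS = {
    "lr_drop_epochs", "scale_range", "stature_range_mm", "fx_range",
    "fy_range", "depth_range_mm", "lateral_range_mm", "elbow_flexion_deg",
    "knee_flexion_deg", "yaw_range_deg",
}


@dataclass
class RunConfig:
    """Top-level configuration for the command-line workflows."""

    synth: SynthConfig = field(default_factory=SynthConfig)
    model: ModelConfig = field(default_factory=desk_model_config)
    train: TrainConfig = field(default_factory=desk_train_config)
    gender: str = "M"
    lp_is_les: bool = False
    seed: int = 0
    out_dir: str = "runs"
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        def fix(cfg_cls, values):
            values = dict(values)
            for f in fields(cfg_cls):
                if f.name in values and f.name in _TUPLE_FIELDS:
                    values[f.name] = tuple(values[f.name])
            return values

        kwargs = dict(d)
        if "synth" in kwargs:
            kwargs["synth"] = SynthConfig(**fix(SynthConfig, kwargs["synth"]))
        if "model" in kwargs:
            kwargs["model"] = ModelConfig(**kwargs["model"])
        if "train" in kwargs:
            tr = fix(TrainConfig, kwargs["train"])
            if isinstance(tr.get("loss_weights"), dict):
                tr["loss_weights"] = LossWeights(**tr["loss_weights"])
            kwargs["train"] = TrainConfig(**tr)
        return cls(**kwargs)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(doc)


def save_config(cfg: RunConfig, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
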