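"""Experiment configuration: one YAML file drives the whole pipeline.

A fixed ``seed`` makes every stage — dataset synthesis, weight init,
shuffling, dropout — reproducible end to end.  Stage boundaries log the
seed, counts and a configuration hash so runs are auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .exceptions import ConfigurationError
from .model import CnnConfig, TrainConfig
from .synthetic import CcGenParams, DatasetConfig, VfGenParams


@dataclass
class ExperimentConfig:
    """Top-level configuration for simulate/train/evaluate/monitor runs."""

    seed: int = 0
    out_dir: str = "runs"
    dataset: DatasetConfig = field(default_factory=DatasetConfig)
    cnn: CnnConfig = field(default_factory=CnnConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    augment: bool = True
    monitor_step_s: float = 0.5

    def __post_init__(self) -> None:
        # the experiment seed cascades into the stage configs
        self.dataset = dataclasses.replace(self.dataset, seed=self.seed)
        self.training = dataclasses.replace(self.training, seed=self.seed)

    def validate(self) -> None:
        self.dataset.validate()
        self.cnn.validate()
        self.training.validate()
        if self.monitor_step_s <= 0:
            raise ConfigurationError("monitor_step_s must be positive")

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "ExperimentConfig":
        def build(dc_type, data):
            if data is None:
                return dc_type()
            fields = {f.name: f for f in dataclasses.fields(dc_type)}
            unknown = set(data) - set(fields)
            if unknown:
                raise ConfigurationError(
                    f"unknown {dc_type.__name__} keys: {sorted(unknown)}")
            kwargs = {}
            for key, val in data.items():
                ftype = fields[key].type
                if isinstance(val, dict) and key in {"vf", "cc"}:
                    val = build(VfGenParams if key == "vf" else CcGenParams, val)
                elif isinstance(val, list):
                    val = tuple(val)
                kwargs[key] = val
            return dc_type(**kwargs)

        cfg = cls(
            seed=int(raw.get("seed", 0)),
            out_dir=str(raw.get("out_dir", "runs")),
            dataset=build(DatasetConfig, raw.get("dataset")),
            cnn=build(CnnConfig, raw.get("cnn")),
            training=build(TrainConfig, raw.get("training")),
            augment=bool(raw.get("augment", True)),
            monitor_step_s=float(raw.get("monitor_step_s", 0.5)),
        )
        cfg.validate()
        return cfg
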