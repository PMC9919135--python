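"""Experiment configuration: one serializable object driving the pipeline."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .gabp import GAConfig
from .simulate import DEFAULT_CONCENTRATIONS_PPB, DEFAULT_FLOWS_SCCM, SimParams

__all__ = ["ExperimentConfig"]


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one end-to-end experiment.

    Round-trips losslessly through YAML or JSON (chosen by file
    extension).
    """

    concentrations_ppb: tuple[float, ...] = DEFAULT_CONCENTRATIONS_PPB
    flows_sccm: tuple[float, ...] = DEFAULT_FLOWS_SCCM
    replicates: int = 2
    sim: SimParams = field(default_factory=SimParams)
    sample_rate_hz: float = 10.0
    duration_s: float = 300.0
    window: int = 51
    span: float = 0.3
    flow_divisor: float = 1000.0
    mr_form: str = "quadratic"
    ga: GAConfig = field(default_factory=GAConfig)
    learning_rate: float = 0.5
    max_epochs: int = 20000
    tolerance: float = 1e-12
    alpha: float = 0.05
    full_scale_ppb: float = 200.0
    threshold_concentration_ppb: float = 50.0
    threshold_flow_sccm: float = 1000.0
    seed: int = 0

    def with_seed(self, seed: int) -> "ExperimentConfig":
        cfg = dataclasses.replace(self, seed=int(seed))
        cfg.sim = dataclasses.replace(cfg.sim, seed=int(seed))
        return cfg

    def to_dict(self) -> dict:
        data = dataclasses.asdict(self)
        data["concentrations_ppb"] = list(self.concentrations_ppb)
        data["flows_sccm"] = list(self.flows_sccm)
        return data

    @classmethod
    def from_dict(cls, data: dict) -> "ExperimentConfig":
        data = dict(data)
        if "sim" in data and isinstance(data["sim"], dict):
            data["sim"] = SimParams(**data["sim"])
        if "ga" in data and isinstance(data["ga"], dict):
            data["ga"] = GAConfig(**data["ga"])
        for key in ("concentrations_ppb", "flows_sccm"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_file(self, path) -> None:
        path = Path(path)
        data = self.to_dict()
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(data, sort_keys=False))
        elif path.suffix == ".json":
            path.write_text(json.dumps(data, indent=2))
        else:
            raise ValueError(f"unknown config extension {path.suffix!r} (use .yaml/.yml/.json)")

    @classmethod
    def from_file(cls, path) -> "ExperimentConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            data = yaml.safe_load(text)
        elif path.suffix == ".json":
            data = json.loads(text)
        else:
            raise ValueError(f"unknown config extension {path.suffix!r} (use .yaml/.yml/.json)")
        return cls.from_dict(data)
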