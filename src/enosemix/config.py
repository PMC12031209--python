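"""Pipeline configuration: one YAML document drives every stage.

Every CLI run writes its fully resolved configuration next to its outputs,
so any artifact can be reproduced from that file plus the recorded seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .model import ModelConfig
from .preprocess import PreprocessParams
from .simulate import CampaignConfig, ExposureScheme, default_schemes
from .training import TrainConfig


@dataclass(frozen=True)
class SimulateBlock:
    schemes: list[str] | None = None      # subset of G1..G7; None = all seven
    repeats: int = 5
    noise_sd: float | None = None         # None = per-sensor defaults (0.01)
    drift_per_hour: float = 0.0
    label_by: str = "composition"
    seed: int = 0

    def campaign(self) -> CampaignConfig:
        available = {s.scheme_id: s for s in default_schemes()}
        if self.schemes is None:
            chosen: tuple[ExposureScheme, ...] = tuple(available.values())
        else:
            unknown = [s for s in self.schemes if s not in available]
            if unknown:
                raise ValueError(f"unknown scheme id(s): {unknown}; "
                                 f"available: {sorted(available)}")
            chosen = tuple(available[s] for s in self.schemes)
        return CampaignConfig(schemes=chosen, repeats=self.repeats,
                              noise_sd=self.noise_sd,
                              drift_per_hour=self.drift_per_hour,
                              label_by=self.label_by)


@dataclass(frozen=True)
class PipelineConfig:
    simulate: SimulateBlock = field(default_factory=SimulateBlock)
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    model: ModelConfig = field(default_factory=ModelConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    cv_folds: int = 5
    cv_seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        def build(klass, block):
            block = dict(block or {})
            if "sigma_init" in block and block["sigma_init"] is not None:
                block["sigma_init"] = tuple(block["sigma_init"])
            return klass(**block)

        return cls(
            simulate=build(SimulateBlock, d.get("simulate")),
            preprocess=build(PreprocessParams, d.get("preprocess")),
            model=build(ModelConfig, d.get("model")),
            training=build(TrainConfig, d.get("training")),
            cv_folds=int(d.get("cv_folds", 5)),
            cv_seed=int(d.get("cv_seed", 0)),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)
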