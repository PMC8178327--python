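"""Pipeline configuration: a strict, schema-validated YAML surface.

Unknown keys are rejected so typos fail fast, before any computation.  All
randomness derives from the single ``cohort.seed``.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .gait_synth import CohortRanges

__all__ = ["PipelineConfig", "CohortConfig", "EnergeticsBlock", "SweepBlock", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CohortConfig(_Strict):
    n: int = Field(default=7, ge=1)
    seed: int = 42
    n_samples: int = Field(default=200, ge=50)
    ranges: dict = Field(default_factory=dict)

    def to_ranges(self) -> CohortRanges:
        known = {f for f in CohortRanges.__dataclass_fields__}
        unknown = set(self.ranges) - known
        if unknown:
            raise ValueError(f"unknown cohort range fields: {sorted(unknown)}")
        return CohortRanges(**{k: tuple(v) for k, v in self.ranges.items()})

    @field_validator("ranges")
    @classmethod
    def _pairs(cls, v):
        for key, rng in v.items():
            if len(rng) != 2:
                raise ValueError(f"range for {key} must be a (low, high) pair")
        return v


class EnergeticsBlock(_Strict):
    heat_coefficient: float = Field(default=0.5, ge=0)
    efficiency: float = Field(default=0.25, gt=0, le=1)


class SweepBlock(_Strict):
    alpha_start: float = 0.0
    alpha_stop: float = 1.5
    alpha_step: float = Field(default=0.1, gt=0)
    alphas: list | None = None  # explicit grid overrides start/stop/step
    sign_tolerance: float = Field(default=0.5, ge=0)


class PipelineConfig(_Strict):
    cohort: CohortConfig = Field(default_factory=CohortConfig)
    model: str = "default"  # "default" or a path to a muscle-model YAML
    energetics: EnergeticsBlock = Field(default_factory=EnergeticsBlock)
    sweep: SweepBlock = Field(default_factory=SweepBlock)
    out_dir: str = "hipexo_out"
    degrees: bool = False  # emit angle files in degrees at the I/O boundary

    def validate_paths(self) -> None:
        if self.model != "default" and not Path(self.model).exists():
            raise FileNotFoundError(f"muscle model file not found: {self.model}")


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = PipelineConfig.model_validate(raw)
    cfg.validate_paths()
    return cfg
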