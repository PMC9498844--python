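"""Run configuration: a validated, fully serializable parameter block.

Every pipeline stage receives a :class:`RunConfig`; the complete
configuration is embedded in every report for provenance.  All randomness
flows through the single ``seed``.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, Field, model_validator

from .synthetic_data import NoiseParams

CONFIG_SCHEMA_VERSION = 1


class RunConfig(BaseModel):
    seed: int = 0
    catalog_seed: int = 2211
    coverage: float = Field(50.0, gt=0)
    fp_rate: float = Field(0.04, ge=0, lt=1)
    fn_rate: float = Field(0.13, ge=0, lt=1)
    sizing_cv: float = Field(0.02, ge=0, lt=1)
    mean_length: float = Field(250_000.0, gt=0)
    min_length: float = Field(150_000.0, ge=0)
    long_mode_min: float = Field(160_000.0, ge=0)
    min_cov: int = Field(5, ge=1)
    min_support: int = Field(3, ge=1)
    min_informative: int = Field(3, ge=1)
    total_target: float | None = None
    report_path: str | None = None

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if self.min_length >= self.mean_length:
            raise ValueError("min_length must be below mean_length")
        return self

    def noise_params(self) -> NoiseParams:
        return NoiseParams(fp_rate=self.fp_rate, fn_rate=self.fn_rate,
                           sizing_cv=self.sizing_cv,
                           mean_length=self.mean_length,
                           min_length=self.min_length,
                           long_mode_min=self.long_mode_min)

    def provenance(self) -> dict:
        return {"schema_version": CONFIG_SCHEMA_VERSION,
                "config": self.model_dump()}

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=False)
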