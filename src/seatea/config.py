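"""Run configuration: a small validated, hashable, serializable record."""

from __future__ import annotations

import hashlib
import json
from typing import Literal

import yaml
from pydantic import BaseModel, Field, field_validator

from .params import PRODUCT_CATEGORIES


class RunConfig(BaseModel):
    """Everything needed to reproduce a pipeline run."""

    n_lat: int = Field(180, ge=8)
    n_lon: int = Field(360, ge=8)
    land_fraction: float = Field(0.3, ge=0.0, lt=1.0)
    n_ports: int = Field(8, ge=1)
    seed: int = 0
    n_sims: int = Field(500, ge=1)
    scenario: Literal["ambient", "limited"] = "ambient"
    categories: tuple[str, ...] = PRODUCT_CATEGORIES
    quantiles: tuple[float, ...] = (5.0, 50.0, 95.0)
    q_step: float = Field(0.01, gt=0.0, le=1.0)
    parameter_table: str | None = None  # path; None = packaged defaults

    @field_validator("categories")
    @classmethod
    def _known_categories(cls, v):
        unknown = set(v) - set(PRODUCT_CATEGORIES)
        if unknown:
            raise ValueError(f"unknown product categories: {sorted(unknown)}")
        return tuple(v)

    @field_validator("quantiles")
    @classmethod
    def _quantiles_in_range(cls, v):
        if any(not 0 < q < 100 for q in v):
            raise ValueError("quantiles must lie strictly between 0 and 100")
        return tuple(float(q) for q in v)

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=True)
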