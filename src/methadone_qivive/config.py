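"""Study configuration: schema-validated YAML with explicit units.

Unknown keys are rejected so silently ignored typos cannot change a run.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator


class MonteCarloSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_per_stratum: int = Field(default=15000, ge=1)
    seed: int = Field(default=1, ge=0, lt=2 ** 31)
    scenarios: list[str] = ["metabolism_only", "multifactor"]

    @field_validator("scenarios")
    @classmethod
    def _known_scenarios(cls, v):
        for s in v:
            if s not in ("metabolism_only", "multifactor"):
                raise ValueError(f"unknown scenario {s!r}")
        return v


class StudyConfig(BaseModel):
    """Top-level settings of an end-to-end run."""

    model_config = ConfigDict(extra="forbid")

    populations: list[str] = ["Caucasian", "Chinese"]
    enantiomers: list[str] = ["R", "S"]
    dose_mg_per_day: float = Field(default=30.0, gt=0)
    n_days: int = Field(default=30, ge=2)
    metabolism_mode: str = "hlm_mm"
    monte_carlo: MonteCarloSettings = MonteCarloSettings()
    csaf_percentiles: list[int] = [95, 99]
    bmr_pct: float = Field(default=10.0, gt=0)
    therapeutic_doses_mg_day: dict[str, float] = {"initial": 10.0,
                                                  "maintenance": 60.0}
    run_reverse_dosimetry: bool = True

    @field_validator("metabolism_mode")
    @classmethod
    def _known_mode(cls, v):
        if v not in ("hlm_mm", "rcyp_mm", "rcyp_interaction"):
            raise ValueError(f"unknown metabolism mode {v!r}")
        return v

    @field_validator("csaf_percentiles")
    @classmethod
    def _known_percentiles(cls, v):
        for p in v:
            if p not in (95, 99):
                raise ValueError("CSAF percentiles must be 95 or 99")
        return v

    def digest(self) -> str:
        """Stable hash of the configuration (provenance)."""
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | Path | None = None) -> StudyConfig:
    """Load a YAML study configuration (defaults when path is None)."""
    if path is None:
        return StudyConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return StudyConfig(**raw)
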