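"""Run configuration: YAML loading, validation, and run manifests.

A single YAML file with one section per pipeline stage; an empty file (or
``None``) yields the full default configuration (20% tax, linear trend,
2014-2023 horizon).  Validation errors name the offending key.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import warnings
from importlib import resources
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator


class ScenarioConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    tax_rate: float = Field(0.20, ge=0.0, le=0.5)
    trend: str = Field("linear", pattern="^(linear|bass)$")
    year_start: int = 2014
    year_end: int = 2023
    ssb_growth: float = Field(0.13, ge=0.0)
    growth_kind: str = Field("increment", pattern="^(increment|compound)$")
    bass_v_start: float = 12.8      # l/person/yr at the horizon start
    bass_v_end: float = 36.3        # l/person/yr at the horizon end
    bass_anchor_year: float = 2012.0
    bass_anchor_value: float = 11.0
    bass_t0: float = 1998.0
    nonbev_kcal_per_year: float = 12.0   # secular non-beverage intake trend

    @field_validator("tax_rate")
    @classmethod
    def _warn_extrapolation(cls, v):
        if v > 0.35:
            warnings.warn(
                "tax rate above the 35% observed price-variation range; "
                "elasticities are extrapolated", stacklevel=2)
        return v

    @field_validator("year_end")
    @classmethod
    def _horizon(cls, v, info):
        start = info.data.get("year_start", 2014)
        if v < start:
            raise ValueError("year_end must be >= year_start")
        return v

    @property
    def years(self) -> range:
        return range(self.year_start, self.year_end + 1)


class MicrosimConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_individuals: int = Field(2000, ge=1)
    n_outer: int = Field(200, ge=2)
    total_population: float = Field(550e6, gt=0)


class GeneratorConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_households: int = Field(100_000, ge=1)
    n_individuals: int = Field(100_000, ge=1)
    bootstrap: int = Field(200, ge=10)


class AppConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    scenario: ScenarioConfig = Field(default_factory=ScenarioConfig)
    microsim: MicrosimConfig = Field(default_factory=MicrosimConfig)
    generator: GeneratorConfig = Field(default_factory=GeneratorConfig)


def load_config(path: str | Path | None = None) -> AppConfig:
    """Load and validate a YAML config; missing sections get defaults."""
    if path is None:
        return AppConfig()
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        return AppConfig()
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    return AppConfig.model_validate(raw)


def dump_config(config: AppConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.model_dump(), sort_keys=False))


def _data_hashes() -> dict[str, str]:
    out = {}
    data = resources.files("ssbtax") / "data"
    for entry in sorted(data.iterdir(), key=lambda e: e.name):
        if entry.name.endswith((".csv", ".json", ".yaml")):
            out[entry.name] = hashlib.sha256(entry.read_bytes()).hexdigest()[:16]
    return out


def run_manifest(seed: int, config: AppConfig | None = None,
                 extra: dict | None = None) -> dict:
    """Everything needed to reproduce a run bit-for-bit."""
    from . import __version__
    return {
        "package_version": __version__,
        "seed": int(seed),
        "timestamp": _dt.datetime.now(_dt.timezone.utc).isoformat(),
        "config": (config or AppConfig()).model_dump(),
        "data_hashes": _data_hashes(),
        **(extra or {}),
    }


def write_manifest(path: str | Path, manifest: dict) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
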