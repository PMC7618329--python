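"""Run configuration: YAML with strict (typo-rejecting) key validation."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .dlnm import ModelConfig
from .errors import SchemaError
from .indices import WHO_2021_SHORT_TERM
from .simulate import SimulationConfig
from .validation import ValidationConfig

__all__ = ["RunConfig", "load_config", "config_hash"]


@dataclass
class PathsConfig:
    data_dir: str = "data/cities"
    output_dir: str = "results"


@dataclass
class IndicesConfig:
    epa_dialect: str = "pre2024"
    eea_edition: str = "2023"
    who_guidelines: dict = field(default_factory=lambda: dict(WHO_2021_SHORT_TERM))
    drf_exposure: str = "ma3"


@dataclass
class FiltersConfig:
    max_date: str | None = None        # e.g. "2019-12-31" to drop later days
    impute_missing: bool = False
    impute_df_per_year: int = 7


@dataclass
class ValidationSection:
    train_fraction: float = 0.7
    n_boot: int = 50
    block_length: int = 30
    seed: int = 0
    min_test_days: int = 365


@dataclass
class RunConfig:
    paths: PathsConfig = field(default_factory=PathsConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    validation: ValidationSection = field(default_factory=ValidationSection)
    indices: IndicesConfig = field(default_factory=IndicesConfig)
    filters: FiltersConfig = field(default_factory=FiltersConfig)

    def validation_config(self) -> ValidationConfig:
        return ValidationConfig(
            train_fraction=self.validation.train_fraction,
            model=self.model,
            n_boot=self.validation.n_boot,
            block_length=self.validation.block_length,
            seed=self.validation.seed,
            min_test_days=self.validation.min_test_days,
            epa_dialect=self.indices.epa_dialect,
            who_guidelines=tuple(self.indices.who_guidelines.items()),
            drf_exposure=self.indices.drf_exposure,
        )


def _build(cls, payload, where):
    if payload is None:
        payload = {}
    if not isinstance(payload, dict):
        raise SchemaError(f"{where}: expected a mapping")
    names = {f.name: f for f in dataclasses.fields(cls)}
    unknown = sorted(set(payload) - set(names))
    if unknown:
        raise SchemaError(f"{where}: unknown key(s) {unknown}")
    kwargs = {}
    for key, value in payload.items():
        f = names[key]
        if dataclasses.is_dataclass(f.type) if isinstance(f.type, type) else False:
            kwargs[key] = _build(f.type, value, f"{where}.{key}")
        elif isinstance(value, list):
            kwargs[key] = tuple(tuple(v) if isinstance(v, list) else v for v in value)
        else:
            kwargs[key] = value
    return cls(**kwargs)


_SECTIONS = {
    "paths": PathsConfig,
    "simulation": SimulationConfig,
    "model": ModelConfig,
    "validation": ValidationSection,
    "indices": IndicesConfig,
    "filters": FiltersConfig,
}


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise SchemaError("config root must be a mapping")
    unknown = sorted(set(raw) - set(_SECTIONS))
    if unknown:
        raise SchemaError(f"unknown top-level config section(s) {unknown}")
    kwargs = {name: _build(cls, raw.get(name), name) for name, cls in _SECTIONS.items()}
    return RunConfig(**kwargs)


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]
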