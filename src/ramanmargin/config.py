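"""Validated run configuration for the end-to-end pipeline.

A run is described by a YAML document (or an in-memory dict) validated with
pydantic.  Every numeric default of the pipeline appears in the bundled
``data/default_config.yaml`` — there are no hidden constants — and CLI flags
override config values.  The configuration hash recorded in each run
manifest is the SHA-256 of the canonical JSON form.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, ValidationError

from .errors import ConfigError


class SimulateSection(BaseModel):
    n_healthy: int = Field(28, ge=0)
    n_tumor: int = Field(29, ge=0)
    n_mixed: int = Field(0, ge=0)
    transit: Optional[list[Literal["healthy", "tumor", "mixed"]]] = None
    noise_sd: float = Field(0.3, ge=0)
    amp_cv: float = Field(0.015, ge=0)
    pool_cv: float = Field(0.22, ge=0)
    cosmic_ray_rate: float = Field(0.1, ge=0)
    dye_probability: float = Field(0.0, ge=0, le=1)
    dye_amplitude: float = Field(15.0, ge=0)
    mixed_fraction: float = Field(0.5, ge=0, le=1)


class PreprocessSection(BaseModel):
    despike_window: int = Field(7, ge=3)
    z_threshold: float = Field(10.0, gt=0)
    rel_threshold: float = Field(0.5, ge=0)
    window_width: float = Field(200.0, gt=0)
    step: float = Field(100.0, gt=0)
    quantile: float = Field(0.10, gt=0, lt=1)
    max_iter: int = Field(20, ge=1)
    tol: float = Field(1e-3, gt=0)
    region: Optional[tuple[float, float]] = None


class BandsSection(BaseModel):
    source: Literal["reference", "select"] = "reference"
    level: float = Field(0.95, gt=0, lt=1)
    min_width: Optional[float] = None
    merge_gap: Optional[float] = None
    top_k: Optional[int] = None
    apply_dye_exclusion: bool = True
    dye_centers: list[float] = [693.0, 1260.0, 1348.0, 1398.0, 1541.0, 1597.0]
    dye_tolerance: float = Field(10.0, gt=0)


class ClassifySection(BaseModel):
    k: int = Field(3, ge=1)
    scale: bool = False
    refit_pca_per_fold: bool = True


class TransitSection(BaseModel):
    threshold: float = Field(0.5, gt=0, lt=1)


class RunConfig(BaseModel):
    seed: int = 0
    excitation_nm: Literal[785, 1064] = 785
    out_dir: str = "runs/demo"
    simulate: SimulateSection = SimulateSection()
    preprocess: PreprocessSection = PreprocessSection()
    bands: BandsSection = BandsSection()
    classify: ClassifySection = ClassifySection()
    transit: TransitSection = TransitSection()

    def canonical_json(self) -> str:
        # out_dir is run placement, not science: identical configurations
        # written to different directories hash identically
        payload = self.model_dump(mode="json")
        payload.pop("out_dir", None)
        return json.dumps(payload, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]


def load_config(source: str | Path | dict | None = None, **overrides) -> RunConfig:
    """Load and validate a run configuration.

    ``source`` may be a YAML path, a dict, or None (bundled defaults).
    Keyword overrides win over the file (nested sections may be dicts).
    Validation failures raise :class:`ConfigError` naming the field.
    """
    if source is None:
        data: dict = {}
    elif isinstance(source, dict):
        data = dict(source)
    else:
        with open(source) as fh:
            data = yaml.safe_load(fh) or {}
    for key, value in overrides.items():
        if value is None:
            continue
        if isinstance(value, dict) and isinstance(data.get(key), dict):
            data[key] = {**data[key], **value}
        else:
            data[key] = value
    try:
        return RunConfig(**data)
    except ValidationError as exc:
        first = exc.errors()[0]
        loc = ".".join(str(p) for p in first["loc"])
        raise ConfigError(f"invalid config field '{loc}': {first['msg']}") from exc


def default_config_path() -> Path:
    """Path of the bundled default configuration YAML."""
    return Path(str(resources.files("ramanmargin").joinpath("data/default_config.yaml")))
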