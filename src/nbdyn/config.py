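"""Structured configuration: YAML in, validated dataclasses out.

Every default traces to the imaging protocol this pipeline reproduces
(80-frame segments, 5 s recovery intervals over 250 s, 0.75/2 um size
classes, ...) or to a documented package design choice.  Unknown keys are
rejected rather than ignored, so a typo cannot silently fall back to a
default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .core import AcquisitionConfig
from .errors import err
from .simulate import DetectorModel, DropletSpec, InterfaceModel


@dataclass(frozen=True)
class MomentsParams:
    segment_len: int = 80
    mean_floor: float = 1.0


@dataclass(frozen=True)
class FrapParams:
    n_prebleach: int = 3
    prebleach_interval: float = 1.3
    postbleach_interval: float = 5.0
    total_postbleach: float = 250.0
    bleach_probability: float = 1.0
    fit_model: str = "single_exp"


@dataclass(frozen=True)
class MorphoParams:
    min_area_um2: float = 0.05
    threshold_method: str = "otsu"
    pixel_size: float = 0.1


@dataclass(frozen=True)
class StatsParams:
    alpha_normality: float = 0.05


@dataclass(frozen=True)
class SimParams:
    n_particles: int = 2000
    immobile_fraction: float = 0.0
    preset: str = "control"


@dataclass(frozen=True)
class PipelineConfig:
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    droplet: DropletSpec = field(default_factory=lambda: DropletSpec(center=(6.75, 6.75), radius=1.5))
    detector: DetectorModel = field(default_factory=DetectorModel)
    interface: InterfaceModel = field(default_factory=InterfaceModel)
    sim: SimParams = field(default_factory=SimParams)
    moments: MomentsParams = field(default_factory=MomentsParams)
    frap: FrapParams = field(default_factory=FrapParams)
    morpho: MorphoParams = field(default_factory=MorphoParams)
    stats: StatsParams = field(default_factory=StatsParams)


def _build(cls, data: dict, path: str):
    if not isinstance(data, dict):
        raise err("invalid_config", f"{path}: expected a mapping")
    names = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(names)
    if unknown:
        raise err("invalid_config", f"{path}: unknown keys {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        ftype = names[key].type
        sub = _SECTION_TYPES.get((cls, key))
        if sub is not None and isinstance(value, dict):
            kwargs[key] = _build(sub, value, f"{path}.{key}")
        else:
            if isinstance(value, list):
                value = tuple(value)
            kwargs[key] = value
    return cls(**kwargs)


_SECTION_TYPES = {
    (PipelineConfig, "acquisition"): AcquisitionConfig,
    (PipelineConfig, "droplet"): DropletSpec,
    (PipelineConfig, "detector"): DetectorModel,
    (PipelineConfig, "interface"): InterfaceModel,
    (PipelineConfig, "sim"): SimParams,
    (PipelineConfig, "moments"): MomentsParams,
    (PipelineConfig, "frap"): FrapParams,
    (PipelineConfig, "morpho"): MorphoParams,
    (PipelineConfig, "stats"): StatsParams,
}


def load_config(path: str | Path) -> PipelineConfig:
    """Read and validate a YAML pipeline configuration."""
    path = Path(path)
    if not path.exists():
        raise err("not_found", str(path))
    data = yaml.safe_load(path.read_text()) or {}
    return _build(PipelineConfig, data, "config")


def dump_config(config: PipelineConfig, path: str | Path | None = None) -> str:
    """Serialize a configuration (the reproducibility record written next
    to every generated dataset)."""
    text = yaml.safe_dump(dataclasses.asdict(config), sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text
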