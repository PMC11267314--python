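"""Pipeline configuration with every tunable threshold in one place."""
from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Any, Mapping

import yaml


@dataclass
class ClassificationConfig:
    softcore_fraction: float = 0.80


@dataclass
class MergeConfig:
    max_distance: int = 50
    max_size_difference: int = 20


@dataclass
class HotspotConfig:
    window: int = 400_000
    step: int = 200_000
    min_count: int = 80
    merge_contiguous: bool = True


@dataclass
class AnnotationConfig:
    promoter_len: int = 2000
    downstream_len: int = 2000


@dataclass
class DEConfig:
    min_abs_log2fc: float = 1.0
    max_p: float = 0.05


@dataclass
class SaturationConfig:
    n_permutations: int = 100
    seed: int = 0


@dataclass
class PipelineConfig:
    classification: ClassificationConfig = field(default_factory=ClassificationConfig)
    merge: MergeConfig = field(default_factory=MergeConfig)
    hotspot: HotspotConfig = field(default_factory=HotspotConfig)
    annotation: AnnotationConfig = field(default_factory=AnnotationConfig)
    de: DEConfig = field(default_factory=DEConfig)
    saturation: SaturationConfig = field(default_factory=SaturationConfig)
    sv_min_len: int = 50

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not 0 < self.classification.softcore_fraction < 1:
            raise ValueError("softcore_fraction must be in (0, 1)")
        for name in ("max_distance", "max_size_difference"):
            if getattr(self.merge, name) < 0:
                raise ValueError(f"merge.{name} must be non-negative")
        if self.hotspot.window < 1 or self.hotspot.step < 1:
            raise ValueError("hotspot window/step must be positive")
        if self.hotspot.step > self.hotspot.window:
            raise ValueError("hotspot step must not exceed window")
        if self.annotation.promoter_len < 1 or self.annotation.downstream_len < 1:
            raise ValueError("annotation flank lengths must be positive")
        if self.sv_min_len < 1:
            raise ValueError("sv_min_len must be positive")
        if self.saturation.n_permutations < 1:
            raise ValueError("saturation.n_permutations must be >= 1")

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "PipelineConfig":
        cfg = cls()
        for f in fields(cls):
            if f.name not in data:
                continue
            value = data[f.name]
            current = getattr(cfg, f.name)
            if isinstance(value, Mapping):
                unknown = set(value) - {sf.name for sf in fields(current)}
                if unknown:
                    raise ValueError(f"unknown keys in {f.name}: {sorted(unknown)}")
                setattr(cfg, f.name, replace(current, **value))
            else:
                setattr(cfg, f.name, value)
        unknown = set(data) - {f.name for f in fields(cls)}
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        cfg.validate()
        return cfg

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, Mapping):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)
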