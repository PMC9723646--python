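"""Pipeline configuration: nested sections per stage, strict key checking.

The resolved configuration (all defaults applied) is serialized next to
every output directory so a run can be reproduced exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from ms2burst.burst_call import BurstCallConfig
from ms2burst.segmentation import SegmentationConfig
from ms2burst.synth import SceneConfig, scene_from_dict, scene_to_dict


@dataclass
class TrackingConfig:
    max_displacement: float = 8.0
    min_track_length: int = 1

    def __post_init__(self) -> None:
        if self.max_displacement <= 0:
            raise ValueError("max_displacement must be > 0")


@dataclass
class StatsConfig:
    control: str = "control"


@dataclass
class PipelineConfig:
    """All stage configurations plus the global seed."""

    scene: SceneConfig = field(default_factory=SceneConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    tracking: TrackingConfig = field(default_factory=TrackingConfig)
    burst: BurstCallConfig = field(default_factory=BurstCallConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    seed: int = 0
    verbosity: str = "info"


def _build_section(cls, data: dict, name: str):
    known = set(cls.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown key(s) in section {name!r}: {sorted(unknown)}")
    converted = dict(data)
    for key in ("expected_count", "size_bounds", "crop_box"):
        if key in converted and converted[key] is not None:
            converted[key] = tuple(converted[key])
    return cls(**converted)


def config_from_dict(data: dict) -> PipelineConfig:
    sections = {
        "scene": lambda d: scene_from_dict(d),
        "segmentation": lambda d: _build_section(SegmentationConfig, d, "segmentation"),
        "tracking": lambda d: _build_section(TrackingConfig, d, "tracking"),
        "burst": lambda d: _build_section(BurstCallConfig, d, "burst"),
        "stats": lambda d: _build_section(StatsConfig, d, "stats"),
    }
    scalars = {"seed", "verbosity"}
    unknown = set(data) - set(sections) - scalars
    if unknown:
        raise ValueError(f"unknown top-level config key(s): {sorted(unknown)}")
    kwargs = {}
    for name, builder in sections.items():
        if name in data:
            kwargs[name] = builder(data[name] or {})
    for name in scalars:
        if name in data:
            kwargs[name] = data[name]
    return PipelineConfig(**kwargs)


def config_to_dict(config: PipelineConfig) -> dict:
    d = {
        "scene": scene_to_dict(config.scene),
        "segmentation": asdict(config.segmentation),
        "tracking": asdict(config.tracking),
        "burst": asdict(config.burst),
        "stats": asdict(config.stats),
        "seed": config.seed,
        "verbosity": config.verbosity,
    }
    seg = d["segmentation"]
    for key in ("expected_count", "size_bounds", "crop_box"):
        if seg.get(key) is not None:
            seg[key] = list(seg[key])
    seg["mask_override"] = {}  # arrays are not serialized
    return d


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)
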