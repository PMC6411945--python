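"""Pipeline configuration with documented defaults and YAML round-trip."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

CONFIG_SCHEMA_VERSION = 1


@dataclass
class PreprocessConfig:
    mt_rolling_ball_radius: int = 50  # px, tubulin projections
    comet_rolling_ball_radius: int = 15  # px, at the 3x-upscaled resolution
    upscale_factor: int = 3
    running_average_window: int = 50  # frames


@dataclass
class RidgeConfig:
    sigma: float = 1.5  # px Gaussian derivative scale
    upper_threshold: float = 7.0  # strength seeding lines
    lower_threshold: float = 2.0  # strength for hysteresis continuation
    min_length: float = 6.0  # px
    line_width: int = 1  # px, density rendering


@dataclass
class CometConfig:
    min_cell_area: float = 64.0  # px^2, watershed marker filter
    min_particle_area: float = 4.0  # px^2 at upscaled resolution
    threshold_method: str = "otsu"
    fixed_threshold: float | None = None


@dataclass
class TrackingConfig:
    spot_sigma: float = 1.5  # px
    min_prominence: float = 10.0  # LoG response units
    max_displacement: float = 6.0  # px gate
    min_frames: int = 3


@dataclass
class KymoConfig:
    stabilize: bool = False
    window: int = 50  # frames of temporal running average
    stride: int = 4
    axes: str = "both"  # slicing directions pooled: x, y or both
    trim_boundary: bool = True  # drop partial-window frames before slicing
    speed_estimate: float = 1.0  # px/frame pilot for streak-scale matching
    feature_width: float = 4.0  # px, typical feature cross-section


@dataclass
class IslandConfig:
    min_cells: int = 5


@dataclass
class PipelineConfig:
    """All tunable pipeline parameters plus calibration and seed."""

    schema_version: int = CONFIG_SCHEMA_VERSION
    # calibration: None defers to values embedded in the image file
    pixel_size: float | None = None  # μm per pixel
    frame_interval: float | None = None  # s per frame
    seed: int = 0
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    ridge: RidgeConfig = field(default_factory=RidgeConfig)
    comets: CometConfig = field(default_factory=CometConfig)
    tracking: TrackingConfig = field(default_factory=TrackingConfig)
    kymo: KymoConfig = field(default_factory=KymoConfig)
    islands: IslandConfig = field(default_factory=IslandConfig)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
        return path

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sections = {
            "preprocess": PreprocessConfig, "ridge": RidgeConfig,
            "comets": CometConfig, "tracking": TrackingConfig,
            "kymo": KymoConfig, "islands": IslandConfig,
        }
        kwargs = {}
        for key, val in d.items():
            if key in sections:
                kwargs[key] = sections[key](**val)
            else:
                kwargs[key] = val
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
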