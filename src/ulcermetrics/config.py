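"""Pipeline configuration: every tunable threshold in one flat, serializable record.

Defaults are the documented module defaults; a JSON config file may override any
subset, and unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path


@dataclass
class PipelineConfig:
    # sticker detection
    green_ratio: float = 1.3          # G must exceed ratio * R and ratio * B
    green_min: int = 60               # minimum G channel value (8-bit)
    sticker_min_area_px: int = 50
    sticker_min_circularity: float = 0.7
    sticker_ambiguity_fraction: float = 0.2   # runner-up within 20% of winner
    sticker_diameter_cm: float = 1.0

    # foot segmentation
    foot_opening_size: int = 3        # square structuring element side, px
    foot_min_fraction: float = 0.02   # largest component must cover >= 2% of frame

    # healing assessment
    assessment_day: int = 28          # 4 weeks of care
    assessment_window_days: int = 3   # accept measurements within +/- this
    on_track_reduction_pct: float = 50.0   # strict > threshold

    # capture guidance
    fraction_lo: float = 0.25
    fraction_hi: float = 0.45
    center_tolerance_frac: float = 0.10    # of min image dimension, px tolerance
    stability_frames: int = 3

    # misc
    seed: int = 0
    out_dir: str = "."

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        data = json.loads(Path(path).read_text())
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


DEFAULT_CONFIG = PipelineConfig()
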