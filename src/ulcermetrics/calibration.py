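"""Fiducial-sticker scale calibration.

The capture protocol places a solid green sticker of known physical diameter
(1 cm) on intact skin; detecting it converts pixel measurements to
centimeters. Detection is a per-pixel green-dominance classification followed
by connected-component filtering on area and circularity.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.measure import perimeter as _perimeter

from .config import DEFAULT_CONFIG, PipelineConfig
from .errors import AmbiguousSticker, NoStickerFound

_EIGHT = np.ones((3, 3), dtype=int)


@dataclass
class ScaleEstimate:
    """Detected sticker geometry and the derived pixels-per-cm factor."""

    pixels_per_cm: float
    sticker_center_px: tuple[float, float]
    sticker_diameter_px: float
    circularity: float
    n_candidate_components: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ScaleEstimate":
        d = json.loads(Path(path).read_text())
        d["sticker_center_px"] = tuple(d["sticker_center_px"])
        return cls(**d)


def classify_green(
    image: np.ndarray, config: PipelineConfig = DEFAULT_CONFIG
) -> np.ndarray:
    """Per-pixel green-dominance mask: G > ratio*R, G > ratio*B, G >= floor.

    A pure pointwise rule with no spatial context; skin, ulcer and dark
    background all fail it while the sticker passes.
    """
    img = np.asarray(image, dtype=np.float64)
    r, g, b = img[..., 0], img[..., 1], img[..., 2]
    return (
        (g > config.green_ratio * r)
        & (g > config.green_ratio * b)
        & (g >= config.green_min)
    )


def _circularity(mask: np.ndarray) -> float:
    """4πA/P² with P from the weighted chain-code perimeter estimator,
    clipped to [0, 1]. A rasterized disc scores ≈ 0.92-0.96."""
    area = float(mask.sum())
    p = float(_perimeter(mask, neighborhood=4))
    if p <= 0:
        return 1.0 if area > 0 else 0.0
    return float(min(1.0, 4.0 * np.pi * area / p**2))


def detect_sticker(
    image: np.ndarray, config: PipelineConfig = DEFAULT_CONFIG
) -> ScaleEstimate:
    """Find the 1-cm sticker and return the pixel/cm scale.

    8-connected components of the green mask are filtered by minimum area and
    circularity; the largest survivor is the sticker. Its diameter is the
    equivalent-circle diameter 2·sqrt(A/π) — robust to ragged rasterized
    edges — and pixels_per_cm = diameter / physical diameter.

    Raises NoStickerFound when nothing survives and AmbiguousSticker when the
    runner-up's area is within the ambiguity fraction of the winner's.
    """
    green = classify_green(image, config)
    labels, n = ndimage.label(green, structure=_EIGHT)
    survivors: list[tuple[float, float, np.ndarray]] = []  # (area, circ, mask)
    for idx in range(1, n + 1):
        comp = labels == idx
        area = float(comp.sum())
        if area < config.sticker_min_area_px:
            continue
        circ = _circularity(comp)
        if circ < config.sticker_min_circularity:
            continue
        survivors.append((area, circ, comp))
    if not survivors:
        raise NoStickerFound(
            f"no green component with area >= {config.sticker_min_area_px} px "
            f"and circularity >= {config.sticker_min_circularity}"
        )
    survivors.sort(key=lambda t: -t[0])
    area, circ, comp = survivors[0]
    if len(survivors) > 1:
        runner_up = survivors[1][0]
        if abs(area - runner_up) <= config.sticker_ambiguity_fraction * area:
            raise AmbiguousSticker(
                f"two sticker candidates with areas {area:.0f} and "
                f"{runner_up:.0f} px"
            )
    rows, cols = np.nonzero(comp)
    diameter = 2.0 * float(np.sqrt(area / np.pi))
    return ScaleEstimate(
        pixels_per_cm=diameter / config.sticker_diameter_cm,
        sticker_center_px=(float(rows.mean()), float(cols.mean())),
        sticker_diameter_px=diameter,
        circularity=circ,
        n_candidate_components=len(survivors),
    )


def px_area_to_cm2(area_px: float, scale: ScaleEstimate) -> float:
    """Convert a pixel area to cm² via the calibrated scale."""
    if scale.pixels_per_cm <= 0:
        raise ValueError("pixels_per_cm must be positive")
    if area_px < 0:
        raise ValueError("area_px must be nonnegative")
    return float(area_px) / scale.pixels_per_cm**2
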