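"""Synthetic foot-photo fixtures with exact ground truth.

Emulates the controlled capture protocol of flash-lit plantar wound
photography: a bright foot on a dark background, a reddish ulcer on the sole
and a 1-cm green fiducial sticker on intact skin. Scenes come with the exact
rasterized masks used to render them, so segmentation and measurement code can
be scored against noise-free truth. Also generates longitudinal healing series
(geometric weekly area reduction) and pinhole-camera height sweeps for the
capture-guidance logic.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .config import DEFAULT_CONFIG
from .errors import GeometryError
from .imageops import (
    disc_mask,
    ellipse_mask,
    luminance,
    polygon_area,
    polygon_mask,
    write_image,
    write_mask,
)

# Fixture palette. Chosen so the sticker passes the green-dominance rule, the
# skin and ulcer fail it, and foot-background luminance contrast stays >= 80.
SKIN_RGB = (210, 170, 140)
ULCER_RGB = (150, 40, 40)
STICKER_RGB = (30, 200, 60)
BACKGROUND_LUMINANCE = 15

#: Physical sticker diameter in cm; fixed by the capture protocol.
STICKER_DIAMETER_CM = 1.0


def _default_ulcer_vertices():
    return [
        (96.0, 78.0),
        (104.0, 102.0),
        (126.0, 110.0),
        (142.0, 94.0),
        (138.0, 72.0),
        (116.0, 64.0),
    ]


@dataclass(frozen=True)
class SceneParams:
    """Full geometric and photometric description of one synthetic scene."""

    image_height_px: int = 240
    image_width_px: int = 320
    foot_semi_axes_px: tuple[float, float] = (95.0, 130.0)  # (rows, cols)
    foot_center_px: tuple[float, float] = (120.0, 160.0)
    foot_luminance: int = 178
    background_luminance: int = BACKGROUND_LUMINANCE
    ulcer_vertices_px: list = field(default_factory=_default_ulcer_vertices)
    ulcer_color: tuple[int, int, int] = ULCER_RGB
    sticker_center_px: tuple[float, float] = (120.0, 240.0)
    sticker_radius_px: float = 20.0
    sticker_color: tuple[int, int, int] = STICKER_RGB
    noise_sigma: float = 0.0
    illumination_gradient: float = 0.0  # luminance slope per row
    seed: int = 0


@dataclass
class SceneTruth:
    """Rendered scene plus the exact masks and derived physical truth."""

    image: np.ndarray
    foot_mask: np.ndarray
    ulcer_mask: np.ndarray
    sticker_mask: np.ndarray
    true_pixels_per_cm: float
    true_ulcer_area_cm2: float
    true_foot_area_px: int
    analytic_ulcer_area_cm2: float
    params: SceneParams


def _foot_color(foot_lum: int) -> np.ndarray:
    """Scale the fixture skin tone so its Rec.601 luminance equals foot_lum."""
    base = np.array(SKIN_RGB, dtype=np.float64)
    base_lum = float(luminance(base.reshape(1, 1, 3))[0, 0])
    return np.clip(base * (foot_lum / base_lum), 0, 255)


def _validate(params: SceneParams, foot, ulcer, sticker) -> None:
    h, w = params.image_height_px, params.image_width_px
    (r0, c0), (a, b) = params.foot_center_px, params.foot_semi_axes_px
    if a <= 0 or b <= 0 or params.sticker_radius_px <= 0:
        raise GeometryError("semi-axes and sticker radius must be positive")
    if r0 - a < 0 or r0 + a > h - 1 or c0 - b < 0 or c0 + b > w - 1:
        raise GeometryError("foot ellipse extends beyond image bounds")
    if not ulcer.any():
        raise GeometryError("ulcer polygon rasterizes to zero pixels")
    if (ulcer & ~foot).any():
        raise GeometryError("ulcer polygon not strictly inside foot ellipse")
    if (sticker & ~foot).any():
        raise GeometryError("sticker disc not inside foot ellipse")
    if (sticker & ulcer).any():
        raise GeometryError("sticker disc overlaps ulcer polygon")
    if params.foot_luminance - params.background_luminance < 80:
        raise GeometryError("insufficient foot/background contrast (< 80)")
    r, g, bch = params.sticker_color
    cfg = DEFAULT_CONFIG
    if not (g > cfg.green_ratio * r and g > cfg.green_ratio * bch and g >= cfg.green_min):
        raise GeometryError("sticker color is not green-dominant")
    if params.noise_sigma < 0:
        raise GeometryError("noise_sigma must be nonnegative")


def generate_scene(params: SceneParams) -> SceneTruth:
    """Render one scene and return it with exact ground-truth masks.

    Masks are captured before noise and illumination are applied, so they are
    the exact rasterized shapes. Deterministic for a fixed seed.
    """
    h, w = params.image_height_px, params.image_width_px
    foot = ellipse_mask(params.foot_center_px, params.foot_semi_axes_px, h, w)
    ulcer = polygon_mask(params.ulcer_vertices_px, h, w)
    sticker = disc_mask(params.sticker_center_px, params.sticker_radius_px, h, w)
    _validate(params, foot, ulcer, sticker)

    img = np.empty((h, w, 3), dtype=np.float64)
    img[...] = params.background_luminance
    img[foot] = _foot_color(params.foot_luminance)
    img[ulcer] = params.ulcer_color
    img[sticker] = params.sticker_color

    if params.illumination_gradient != 0.0:
        ramp = params.illumination_gradient * (
            np.arange(h, dtype=np.float64) - (h - 1) / 2.0
        )
        img += ramp[:, None, None]
    if params.noise_sigma > 0:
        rng = np.random.default_rng(params.seed)
        img += rng.normal(0.0, params.noise_sigma, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    ppcm = 2.0 * params.sticker_radius_px / STICKER_DIAMETER_CM
    return SceneTruth(
        image=img,
        foot_mask=foot,
        ulcer_mask=ulcer,
        sticker_mask=sticker,
        true_pixels_per_cm=ppcm,
        true_ulcer_area_cm2=float(ulcer.sum()) / ppcm**2,
        true_foot_area_px=int(foot.sum()),
        analytic_ulcer_area_cm2=polygon_area(params.ulcer_vertices_px) / ppcm**2,
        params=params,
    )


def _scale_polygon(vertices, factor: float):
    verts = np.asarray(vertices, dtype=np.float64)
    centroid = verts.mean(axis=0)
    return [tuple(p) for p in (centroid + factor * (verts - centroid))]


def generate_healing_series(
    initial_area_cm2: float,
    weekly_reduction_fraction: float,
    n_weeks: int,
    base_params: SceneParams | None = None,
    seed: int = 0,
) -> list[tuple[int, SceneTruth]]:
    """Weekly scenes whose ulcer shrinks geometrically.

    Week ``w`` scales the base ulcer polygon about its centroid so the
    analytic area equals ``initial_area_cm2 * (1 - f)**w``; the rasterized
    area tracks it within the 3% rasterization tolerance for shapes of a few
    hundred pixels or more.
    """
    if n_weeks < 1:
        raise ValueError("n_weeks must be >= 1")
    if not (0.0 <= weekly_reduction_fraction < 1.0):
        raise ValueError("weekly_reduction_fraction must be in [0, 1)")
    if base_params is None:
        base_params = SceneParams()
    ppcm = 2.0 * base_params.sticker_radius_px / STICKER_DIAMETER_CM
    base_area_px = polygon_area(base_params.ulcer_vertices_px)
    series: list[tuple[int, SceneTruth]] = []
    for week in range(n_weeks + 1):
        target_px = initial_area_cm2 * (1.0 - weekly_reduction_fraction) ** week * ppcm**2
        factor = float(np.sqrt(target_px / base_area_px))
        verts = _scale_polygon(base_params.ulcer_vertices_px, factor)
        params = replace(
            base_params,
            ulcer_vertices_px=verts,
            seed=int((seed + week) % 2**31),
        )
        series.append((7 * week, generate_scene(params)))
    return series


def generate_capture_sweep(
    heights_cm: Sequence[float],
    foot_true_length_cm: float = 24.0,
    camera_model: float = 130.0,
    base_params: SceneParams | None = None,
    center_offset_px: tuple[float, float] = (0.0, 0.0),
) -> list[np.ndarray]:
    """Frames of the foot hovering at given heights over an upward camera.

    Pinhole model: apparent length in px = camera_model * foot_true_length_cm
    / height_cm, so silhouette area scales as 1/height². The whole scene
    (foot, ulcer, sticker) is scaled about the foot center and re-centered in
    the frame plus ``center_offset_px``.
    """
    if any(h <= 0 for h in heights_cm):
        raise ValueError("heights must be strictly positive")
    if base_params is None:
        base_params = SceneParams()
    h, w = base_params.image_height_px, base_params.image_width_px
    a0, b0 = base_params.foot_semi_axes_px
    base_len_px = 2.0 * max(a0, b0)
    center = (
        (h - 1) / 2.0 + center_offset_px[0],
        (w - 1) / 2.0 + center_offset_px[1],
    )
    c_old = np.asarray(base_params.foot_center_px)
    frames = []
    for height in heights_cm:
        k = (camera_model * foot_true_length_cm / height) / base_len_px
        verts = [
            tuple(np.asarray(center) + k * (np.asarray(v) - c_old))
            for v in base_params.ulcer_vertices_px
        ]
        sticker_center = tuple(
            np.asarray(center) + k * (np.asarray(base_params.sticker_center_px) - c_old)
        )
        params = replace(
            base_params,
            foot_center_px=center,
            foot_semi_axes_px=(k * a0, k * b0),
            ulcer_vertices_px=verts,
            sticker_center_px=sticker_center,
            sticker_radius_px=k * base_params.sticker_radius_px,
        )
        frames.append(generate_scene(params).image)
    return frames


def random_scene_params(
    rng: np.random.Generator,
    sticker_radius_px: float | None = None,
    noise_sigma: float = 0.0,
    image_shape: tuple[int, int] = (240, 320),
) -> SceneParams:
    """Draw a random valid scene: jittered foot ellipse, star-convex ulcer
    polygon toward the toe, sticker toward the heel sized 10-60 px.

    Deterministic given the generator state; every draw satisfies the scene
    invariants by construction (sticker kept inside the ellipse and >= 10 px
    clear of the ulcer).
    """
    h, w = image_shape
    r0, c0 = h / 2.0, w / 2.0
    a = rng.uniform(0.36 * h, 0.42 * h)
    b = rng.uniform(0.38 * w, 0.44 * w)
    if sticker_radius_px is None:
        sticker_radius_px = rng.uniform(10.0, 60.0)
    r = float(sticker_radius_px)

    # ulcer: star-convex polygon around a center on the toe side; vertex
    # angles are evenly spaced with jitter so the outline is irregular but
    # never a degenerate sliver (area stays well above 400 px)
    n_vert = int(rng.integers(5, 9))
    ulcer_center = np.array([r0, c0 - 0.55 * b])
    spacing = 2 * np.pi / n_vert
    angles = spacing * np.arange(n_vert) + rng.uniform(
        -0.35 * spacing, 0.35 * spacing, size=n_vert
    )
    radii = rng.uniform(14.0, 26.0, size=n_vert)
    verts = [
        (ulcer_center[0] + rad * np.sin(t), ulcer_center[1] + rad * np.cos(t))
        for t, rad in zip(angles, radii)
    ]

    # sticker: as far toward the heel as fits inside the ellipse with margin,
    # shrunk back until the inflated disc clears both ellipse and ulcer
    d = (b - r) * 0.8
    theta = np.linspace(0, 2 * np.pi, 256)
    while d > 0:
        worst = np.max(
            ((d + (r + 2) * np.cos(theta)) / b) ** 2
            + (((r + 2) * np.sin(theta)) / a) ** 2
        )
        if worst <= 1.0:
            break
        d *= 0.9
    sticker_center = (r0, c0 + d)
    gap = np.hypot(*(np.array(sticker_center) - ulcer_center)) - r - radii.max()
    if gap < 10.0:
        raise GeometryError("cannot place sticker >= 10 px from ulcer")
    return SceneParams(
        image_height_px=h,
        image_width_px=w,
        foot_semi_axes_px=(a, b),
        foot_center_px=(r0, c0),
        ulcer_vertices_px=verts,
        sticker_center_px=sticker_center,
        sticker_radius_px=r,
        noise_sigma=noise_sigma,
        seed=int(rng.integers(0, 2**31)),
    )


def write_scene(truth: SceneTruth, out_dir: str | Path) -> dict:
    """Write image, masks and truth.json; return the truth dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_image(out / "image.png", truth.image)
    write_mask(out / "foot_mask.png", truth.foot_mask)
    write_mask(out / "ulcer_mask.png", truth.ulcer_mask)
    write_mask(out / "sticker_mask.png", truth.sticker_mask)
    record = asdict(truth.params)
    record.update(
        true_pixels_per_cm=truth.true_pixels_per_cm,
        true_ulcer_area_cm2=truth.true_ulcer_area_cm2,
        true_foot_area_px=truth.true_foot_area_px,
        analytic_ulcer_area_cm2=truth.analytic_ulcer_area_cm2,
    )
    (out / "truth.json").write_text(json.dumps(record, indent=2, default=float))
    return record


def write_series_manifest(
    series: list[tuple[int, SceneTruth]], out_dir: str | Path
) -> Path:
    """Write each scene under week_<d>/ plus a manifest CSV."""
    out = Path(out_dir)
    rows = []
    for day, truth in series:
        scene_dir = out / f"day_{day:03d}"
        write_scene(truth, scene_dir)
        rows.append(
            {
                "day_offset": day,
                "image_path": str(scene_dir / "image.png"),
                "true_area_cm2": truth.analytic_ulcer_area_cm2,
            }
        )
    path = out / "series.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
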