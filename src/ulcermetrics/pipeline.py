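"""End-to-end composition: photo + scribbles → dated wound measurement.

Also hosts the one-command demo that generates a synthetic healing series,
analyzes every time point and writes the progress artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import os
import tempfile
from datetime import date, timedelta
from pathlib import Path

import numpy as np

from .calibration import detect_sticker
from .config import DEFAULT_CONFIG, PipelineConfig
from .foot import segment_foot
from .imageops import write_image, write_mask
from .metrics import (
    ProgressSeries,
    WoundMeasurement,
    assess_healing,
    measure,
    plot_progress,
)
from .synthetic import SceneParams, generate_healing_series
from .ulcer import ScribbleSet, overlay_contour, rasterize_scribbles, watershed_segment


def analyze_image(
    image: np.ndarray,
    scribbles: ScribbleSet,
    when: date,
    config: PipelineConfig = DEFAULT_CONFIG,
):
    """calibrate → segment foot → watershed ulcer → measure.

    Returns (measurement, scale, foot_seg, ulcer_seg, overlay image).
    """
    scale = detect_sticker(image, config)
    foot_seg = segment_foot(image, config)
    markers = rasterize_scribbles(scribbles, *image.shape[:2])
    ulcer_seg = watershed_segment(image, markers, foot_seg.foot_mask)
    m = measure(ulcer_seg, foot_seg, scale, when)
    overlay = overlay_contour(image, ulcer_seg.boundary_contour)
    return m, scale, foot_seg, ulcer_seg, overlay


def append_measurement_csv(path: str | Path, m: WoundMeasurement) -> None:
    """Append one row atomically (write full file to temp, then rename)."""
    path = Path(path)
    if path.exists():
        series = ProgressSeries.from_csv(path)
        ms = series.measurements + [m]
    else:
        ms = [m]
    ms.sort(key=lambda x: x.date)
    fd, tmp = tempfile.mkstemp(dir=path.parent or ".", suffix=".csv")
    os.close(fd)
    try:
        ProgressSeries(ms).to_csv(tmp)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def default_scribbles(truth, margin_px: int = 5) -> ScribbleSet:
    """Construct 'correct' scribbles from a synthetic scene's ground truth.

    The ulcer stroke traces the boundary of the true mask eroded by
    ``margin_px`` and the skin stroke traces the dilated boundary, emulating
    a user circling inside and around the wound while staying a safe margin
    from its true edge.
    """
    from scipy import ndimage

    from .ulcer import extract_boundary

    mask = truth.ulcer_mask
    r = np.arange(-margin_px, margin_px + 1)
    disc = (r[:, None] ** 2 + r[None, :] ** 2) <= margin_px**2
    inner = ndimage.binary_erosion(mask, structure=disc)
    outer = ndimage.binary_dilation(mask, structure=disc)
    if inner.any():
        labels, n = ndimage.label(inner, structure=np.ones((3, 3), dtype=int))
        if n > 1:  # erosion may split a concave wound; keep the biggest lobe
            sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
            inner = labels == (int(np.argmax(sizes)) + 1)
        ulcer_stroke = extract_boundary(inner)
    else:
        rows, cols = np.nonzero(mask)
        ulcer_stroke = [(int(round(rows.mean())), int(round(cols.mean())))]
    return ScribbleSet(
        skin_stroke=extract_boundary(outer), ulcer_stroke=ulcer_stroke
    )


def run_demo(
    seed: int,
    out_dir: str | Path,
    weekly_reduction: float = 0.25,
    initial_area_cm2: float = 2.0,
    n_weeks: int = 4,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> dict:
    """Generate a 5-point healing series, analyze every time point, and write
    the measurement log, progress plot and healing assessment report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    series = generate_healing_series(
        initial_area_cm2, weekly_reduction, n_weeks, SceneParams(), seed=seed
    )
    start = date(2026, 1, 1)
    measurements = []
    for day, truth in series:
        m, scale, foot_seg, ulcer_seg, overlay = analyze_image(
            truth.image, default_scribbles(truth), start + timedelta(days=day), config
        )
        scene_dir = out / f"day_{day:03d}"
        scene_dir.mkdir(exist_ok=True)
        write_image(scene_dir / "image.png", truth.image)
        write_image(scene_dir / "overlay.png", overlay)
        write_mask(scene_dir / "ulcer_mask.png", ulcer_seg.ulcer_mask)
        measurements.append(m)
    progress = ProgressSeries(measurements)
    progress.to_csv(out / "measurements.csv")
    plot_progress(progress, out / "progress.png")
    assessment = assess_healing(progress, config)
    report = dataclasses.asdict(assessment)
    report["baseline_date"] = assessment.baseline_date.isoformat()
    report["assessment_date"] = assessment.assessment_date.isoformat()
    (out / "assessment.json").write_text(json.dumps(report, indent=2))
    return report
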