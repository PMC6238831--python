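"""Voice-assistance capture guidance, as a symbolic state machine.

The phone lies camera-up on the floor and the patient hovers the foot above
it. Each frame is analyzed for the foot silhouette's areal fraction of the
frame and its centroid offset; the session emits symbolic tokens instead of
speech. Because the camera faces upward, a silhouette that is too LARGE means
the foot is too CLOSE, so the instruction is HIGHER (raise the foot), and a
too-small silhouette yields LOWER. Capture triggers after a run of k
consecutive frames that are both in the size band and centered.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .config import DEFAULT_CONFIG, PipelineConfig
from .errors import NoFootFound
from .foot import segment_foot


class GuidanceSignal(str, Enum):
    HIGHER = "HIGHER"
    LOWER = "LOWER"
    CENTER = "CENTER"
    HOLD = "HOLD"
    CAPTURED = "CAPTURED"
    NO_FOOT = "NO_FOOT"


@dataclass
class FrameMetrics:
    foot_fraction: float
    centroid_offset: tuple[float, float]  # (d_row, d_col) from image center
    foot_found: bool


def analyze_frame(
    image: np.ndarray, config: PipelineConfig = DEFAULT_CONFIG
) -> FrameMetrics:
    """Foot fraction and centroid offset for one frame; a frame with no
    detectable foot yields foot_found=False rather than an error."""
    h, w = image.shape[:2]
    try:
        seg = segment_foot(image, config)
    except NoFootFound:
        return FrameMetrics(0.0, (0.0, 0.0), False)
    center = ((h - 1) / 2.0, (w - 1) / 2.0)
    return FrameMetrics(
        foot_fraction=seg.foot_area_px / (h * w),
        centroid_offset=(
            seg.foot_centroid_px[0] - center[0],
            seg.foot_centroid_px[1] - center[1],
        ),
        foot_found=True,
    )


def center_tolerance_px(image_shape, config: PipelineConfig) -> float:
    return config.center_tolerance_frac * min(image_shape[:2])


def guidance_step(
    metrics: FrameMetrics,
    config: PipelineConfig,
    counter: int,
    tolerance_px: float,
) -> tuple[GuidanceSignal, int]:
    """One decision: returns the token and the updated in-band counter.

    Priority order: no foot, too close (HIGHER), too far (LOWER), off-center
    (CENTER); only a fully compliant frame advances the counter, and any
    other outcome resets it. CAPTURED fires when the counter reaches the
    stability requirement.
    """
    if not metrics.foot_found:
        return GuidanceSignal.NO_FOOT, 0
    if metrics.foot_fraction > config.fraction_hi:
        return GuidanceSignal.HIGHER, 0
    if metrics.foot_fraction < config.fraction_lo:
        return GuidanceSignal.LOWER, 0
    d_row, d_col = metrics.centroid_offset
    if abs(d_row) > tolerance_px or abs(d_col) > tolerance_px:
        return GuidanceSignal.CENTER, 0
    counter += 1
    if counter >= config.stability_frames:
        return GuidanceSignal.CAPTURED, counter
    return GuidanceSignal.HOLD, counter


def run_session(
    frames: list[np.ndarray], config: PipelineConfig = DEFAULT_CONFIG
) -> tuple[list[GuidanceSignal], int | None]:
    """Fold guidance over a frame stream; stop at the first CAPTURED.

    Returns the emitted token sequence and the index of the captured frame
    (None when the stream ends without capture).
    """
    if not frames:
        raise ValueError("empty frame list")
    tolerance = center_tolerance_px(frames[0].shape, config)
    signals: list[GuidanceSignal] = []
    counter = 0
    for i, frame in enumerate(frames):
        token, counter = guidance_step(
            analyze_frame(frame, config), config, counter, tolerance
        )
        signals.append(token)
        if token is GuidanceSignal.CAPTURED:
            return signals, i
    return signals, None
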