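"""Foot-silhouette segmentation.

The flash-lit capture protocol guarantees a bright foot on a dark background
but not absolute levels, so the luminance threshold is chosen per image by
Otsu's method. The wound bed can be darker than skin and fall below the
threshold; enclosed holes are therefore filled so the silhouette includes the
ulcer, giving the downstream ulcer/foot area ratio a well-defined denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .config import DEFAULT_CONFIG, PipelineConfig
from .errors import NoFootFound
from .imageops import luminance

_EIGHT = np.ones((3, 3), dtype=int)


@dataclass
class FootSegmentation:
    foot_mask: np.ndarray
    foot_area_px: int
    foot_centroid_px: tuple[float, float]


def segment_foot(
    image: np.ndarray, config: PipelineConfig = DEFAULT_CONFIG
) -> FootSegmentation:
    """Segment the foot from the dark background.

    Otsu threshold on Rec.601 luminance → small binary opening to suppress
    salt noise → keep the largest 8-connected component → fill enclosed
    holes. Raises NoFootFound when the largest component covers less than
    ``config.foot_min_fraction`` of the frame (or the image is flat).
    """
    lum = luminance(image)
    if lum.max() - lum.min() < 1e-9:
        raise NoFootFound("image has no contrast")
    fg = lum > threshold_otsu(lum)
    k = config.foot_opening_size
    if k > 1:
        fg = ndimage.binary_opening(fg, structure=np.ones((k, k), dtype=bool))
    labels, n = ndimage.label(fg, structure=_EIGHT)
    if n == 0:
        raise NoFootFound("no foreground component")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
    best = int(np.argmax(sizes)) + 1
    if sizes[best - 1] < config.foot_min_fraction * lum.size:
        raise NoFootFound(
            f"largest bright component covers {sizes[best - 1] / lum.size:.1%} "
            f"of the frame (< {config.foot_min_fraction:.0%})"
        )
    mask = ndimage.binary_fill_holes(labels == best)
    rows, cols = np.nonzero(mask)
    return FootSegmentation(
        foot_mask=mask,
        foot_area_px=int(mask.sum()),
        foot_centroid_px=(float(rows.mean()), float(cols.mean())),
    )
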