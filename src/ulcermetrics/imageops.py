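"""Small shared image primitives: luminance, rasterization, PNG round-trips.

Coordinate convention everywhere in this package: (row, col), 0-based, origin
at the top-left; an integer coordinate names the pixel center.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

#: Rec.601 luma weights; the same luminance definition feeds foot thresholding
#: and the watershed relief so the two stages see an identical scalar image.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


def luminance(image: np.ndarray) -> np.ndarray:
    """Rec.601 luminance of an 8-bit RGB image, as float64 in [0, 255]."""
    img = np.asarray(image, dtype=np.float64)
    r, g, b = img[..., 0], img[..., 1], img[..., 2]
    wr, wg, wb = LUMA_WEIGHTS
    return wr * r + wg * g + wb * b


def polygon_mask(vertices, height: int, width: int) -> np.ndarray:
    """Rasterize a polygon: a pixel is inside iff its center passes the
    even-odd (crossing-number) test against the vertex loop.

    ``vertices`` is an ordered list of (row, col) floats; the loop is closed
    implicitly.
    """
    verts = np.asarray(vertices, dtype=np.float64)
    if verts.ndim != 2 or verts.shape[0] < 3:
        raise ValueError("polygon needs at least 3 vertices")
    rows = verts[:, 0]
    cols = verts[:, 1]
    r0 = max(int(np.floor(rows.min())), 0)
    r1 = min(int(np.ceil(rows.max())), height - 1)
    c0 = max(int(np.floor(cols.min())), 0)
    c1 = min(int(np.ceil(cols.max())), width - 1)
    mask = np.zeros((height, width), dtype=bool)
    if r1 < r0 or c1 < c0:
        return mask
    rr, cc = np.mgrid[r0 : r1 + 1, c0 : c1 + 1]
    inside = np.zeros(rr.shape, dtype=bool)
    n = len(verts)
    for i in range(n):
        ra, ca = rows[i], cols[i]
        rb, cb = rows[(i + 1) % n], cols[(i + 1) % n]
        if ra == rb:
            continue  # horizontal edge never crossed by a horizontal ray
        crosses = (ra > rr) != (rb > rr)
        with np.errstate(divide="ignore", invalid="ignore"):
            c_int = ca + (rr - ra) * (cb - ca) / (rb - ra)
        inside ^= crosses & (cc < c_int)
    mask[r0 : r1 + 1, c0 : c1 + 1] = inside
    return mask


def polygon_area(vertices) -> float:
    """Analytic (shoelace) area of a simple polygon in px²."""
    verts = np.asarray(vertices, dtype=np.float64)
    r = verts[:, 0]
    c = verts[:, 1]
    return 0.5 * abs(np.dot(r, np.roll(c, -1)) - np.dot(c, np.roll(r, -1)))


def ellipse_mask(center, semi_axes, height: int, width: int) -> np.ndarray:
    """Filled axis-aligned ellipse; semi_axes = (along rows, along cols)."""
    r0, c0 = center
    a, b = semi_axes
    rr, cc = np.mgrid[0:height, 0:width]
    return ((rr - r0) / a) ** 2 + ((cc - c0) / b) ** 2 <= 1.0


def disc_mask(center, radius: float, height: int, width: int) -> np.ndarray:
    r0, c0 = center
    rr, cc = np.mgrid[0:height, 0:width]
    return (rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2


def write_image(path: str | Path, image: np.ndarray) -> None:
    iio.imwrite(Path(path), np.asarray(image, dtype=np.uint8))


def read_image(path: str | Path) -> np.ndarray:
    img = iio.imread(Path(path))
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    return np.asarray(img[..., :3], dtype=np.uint8)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    iio.imwrite(Path(path), (np.asarray(mask, dtype=bool) * np.uint8(255)))


def read_mask(path: str | Path) -> np.ndarray:
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > 127
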