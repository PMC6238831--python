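"""Scribble-seeded ulcer segmentation.

The user roughly draws one stroke around the ulcer (on skin) and one inside
it; the strokes become watershed markers and a marker-seeded priority flood
over the luminance-gradient relief assigns every foot pixel to skin or ulcer.
The flood is fully deterministic: the priority queue orders by relief value
with FIFO tie-breaking by insertion order, so the output is bit-reproducible.
The resulting ulcer boundary is traced (Moore neighborhood, clockwise) and can
be drawn onto the photo as a green contour line.
"""

from __future__ import annotations

import heapq
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.draw import line as _bresenham

from .errors import (
    EmptyMask,
    MissingMarker,
    MultipleComponents,
    OutOfBounds,
    OverlappingScribbles,
)
from .imageops import luminance

SKIN_LABEL = 1
ULCER_LABEL = 2

# 4-neighbor offsets, fixed order: up, down, left, right. Enqueue order at
# equal relief depends on this, so it is part of the determinism contract.
_N4 = ((-1, 0), (1, 0), (0, -1), (0, 1))


@dataclass
class ScribbleSet:
    """One stroke on skin around the ulcer, one inside the ulcer; ordered
    (row, col) points, consecutive points joined by Bresenham lines."""

    skin_stroke: list[tuple[int, int]]
    ulcer_stroke: list[tuple[int, int]]

    @classmethod
    def from_json(cls, path: str | Path) -> "ScribbleSet":
        d = json.loads(Path(path).read_text())
        return cls(
            skin_stroke=[tuple(p) for p in d["skin_stroke"]],
            ulcer_stroke=[tuple(p) for p in d["ulcer_stroke"]],
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "skin_stroke": [list(map(int, p)) for p in self.skin_stroke],
                    "ulcer_stroke": [list(map(int, p)) for p in self.ulcer_stroke],
                }
            )
        )


@dataclass
class UlcerSegmentation:
    ulcer_mask: np.ndarray
    boundary_contour: list[tuple[int, int]]
    n_ulcer_px: int


def _stroke_pixels(stroke, height, width):
    pts = [(int(r), int(c)) for r, c in stroke]
    for r, c in pts:
        if not (0 <= r < height and 0 <= c < width):
            raise OutOfBounds(f"stroke point ({r}, {c}) outside {height}x{width}")
    pixels: set[tuple[int, int]] = set()
    if len(pts) == 1:
        pixels.add(pts[0])
    for (r0, c0), (r1, c1) in zip(pts, pts[1:]):
        rr, cc = _bresenham(r0, c0, r1, c1)
        pixels.update(zip(rr.tolist(), cc.tolist()))
    return pixels


def rasterize_scribbles(
    scribbles: ScribbleSet, height: int, width: int
) -> np.ndarray:
    """Turn strokes into a marker grid: 0 unlabeled, 1 skin, 2 ulcer."""
    if not scribbles.skin_stroke or not scribbles.ulcer_stroke:
        raise MissingMarker("both skin and ulcer strokes are required")
    skin = _stroke_pixels(scribbles.skin_stroke, height, width)
    ulcer = _stroke_pixels(scribbles.ulcer_stroke, height, width)
    shared = skin & ulcer
    if shared:
        raise OverlappingScribbles(f"strokes share pixels {sorted(shared)[:5]}")
    markers = np.zeros((height, width), dtype=np.int32)
    for r, c in skin:
        markers[r, c] = SKIN_LABEL
    for r, c in ulcer:
        markers[r, c] = ULCER_LABEL
    return markers


def gradient_relief(image: np.ndarray) -> np.ndarray:
    """Relief surface: per-pixel maximum absolute luminance difference to the
    4-neighbors (missing neighbors at the border contribute nothing)."""
    lum = luminance(image) if image.ndim == 3 else np.asarray(image, dtype=np.float64)
    relief = np.zeros_like(lum)
    d = np.abs(np.diff(lum, axis=0))
    relief[:-1] = np.maximum(relief[:-1], d)
    relief[1:] = np.maximum(relief[1:], d)
    d = np.abs(np.diff(lum, axis=1))
    relief[:, :-1] = np.maximum(relief[:, :-1], d)
    relief[:, 1:] = np.maximum(relief[:, 1:], d)
    return relief


def priority_flood(relief: np.ndarray, seeds: np.ndarray) -> np.ndarray:
    """Marker-seeded watershed as a priority flood.

    ``seeds`` holds nonzero labels at seed pixels. The queue is initialized
    with the unlabeled 4-neighbors of every seed pixel (seeds visited in
    row-major scan order, neighbors in up/down/left/right order). Repeatedly
    the entry with the lowest relief — FIFO among equal relief, by insertion
    order — is popped; a still-unlabeled popped pixel takes the label of the
    neighbor that enqueued it and enqueues its own unlabeled neighbors. No
    ridge label is kept: every reachable pixel joins the region that gets to
    it first.
    """
    h, w = relief.shape
    labels = seeds.astype(np.int32, copy=True)
    heap: list[tuple[float, int, int, int, int]] = []
    counter = 0
    for r, c in zip(*np.nonzero(seeds)):
        lab = int(seeds[r, c])
        for dr, dc in _N4:
            nr, nc = r + dr, c + dc
            if 0 <= nr < h and 0 <= nc < w and labels[nr, nc] == 0:
                heapq.heappush(heap, (float(relief[nr, nc]), counter, nr, nc, lab))
                counter += 1
    while heap:
        _, _, r, c, lab = heapq.heappop(heap)
        if labels[r, c] != 0:
            continue
        labels[r, c] = lab
        for dr, dc in _N4:
            nr, nc = r + dr, c + dc
            if 0 <= nr < h and 0 <= nc < w and labels[nr, nc] == 0:
                heapq.heappush(heap, (float(relief[nr, nc]), counter, nr, nc, lab))
                counter += 1
    return labels


def watershed_segment(
    image: np.ndarray, markers: np.ndarray, foot_mask: np.ndarray
) -> UlcerSegmentation:
    """Flood the luminance-gradient relief from the scribble markers.

    Pixels outside the foot silhouette are pre-assigned the skin label before
    flooding, so the ulcer region cannot leak into the background; marker
    pixels always keep their seeded label.
    """
    if not (markers == SKIN_LABEL).any() or not (markers == ULCER_LABEL).any():
        raise MissingMarker("marker grid must contain both labels 1 and 2")
    relief = gradient_relief(image)
    seeds = np.where(foot_mask, 0, SKIN_LABEL).astype(np.int32)
    seeds[markers == SKIN_LABEL] = SKIN_LABEL
    seeds[markers == ULCER_LABEL] = ULCER_LABEL
    labels = priority_flood(relief, seeds)
    ulcer_mask = labels == ULCER_LABEL
    contour = extract_boundary(ulcer_mask) if ulcer_mask.any() else []
    return UlcerSegmentation(
        ulcer_mask=ulcer_mask,
        boundary_contour=contour,
        n_ulcer_px=int(ulcer_mask.sum()),
    )


# Moore neighborhood in clockwise order (screen coordinates, row downward),
# starting at west: W, NW, N, NE, E, SE, S, SW.
_MOORE = ((0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1))
_MOORE_INDEX = {off: i for i, off in enumerate(_MOORE)}


def extract_boundary(mask: np.ndarray) -> list[tuple[int, int]]:
    """Trace the outer boundary of a single-component mask.

    Moore-neighbor tracing, clockwise, starting at the topmost-then-leftmost
    true pixel; the returned contour is closed (first point repeated at the
    end). Terminates when the start pixel is re-entered from the initial
    backtrack direction, which handles one-pixel-wide appendages correctly.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyMask("cannot trace an empty mask")
    from scipy import ndimage

    _, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n > 1:
        raise MultipleComponents(f"mask has {n} components")
    h, w = mask.shape
    rows, cols = np.nonzero(mask)
    start = (int(rows.min()), int(cols[rows == rows.min()].min()))
    contour = [start]
    # backtrack: the false pixel we "came from"; west of start is false
    # because start is the leftmost true pixel of the topmost row
    p, b = start, (start[0], start[1] - 1)
    first_move = None
    while True:
        b_idx = _MOORE_INDEX[(b[0] - p[0], b[1] - p[1])]
        nxt = back = None
        for step in range(1, 9):
            dr, dc = _MOORE[(b_idx + step) % 8]
            q = (p[0] + dr, p[1] + dc)
            if 0 <= q[0] < h and 0 <= q[1] < w and mask[q]:
                pr, pc = _MOORE[(b_idx + step - 1) % 8]
                nxt, back = q, (p[0] + pr, p[1] + pc)
                break
        if nxt is None:  # isolated single pixel
            return [start, start]
        if first_move is None:
            first_move = (p, nxt)
        elif (p, nxt) == first_move:
            break  # about to repeat the very first move: contour is closed
        contour.append(nxt)
        p, b = nxt, back
    return contour


def overlay_contour(image: np.ndarray, contour) -> np.ndarray:
    """Copy of the photo with contour pixels painted pure green."""
    out = np.array(image, copy=True)
    for r, c in contour:
        out[int(r), int(c)] = (0, 255, 0)
    return out
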