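"""Scribble rasterization, the priority-flood watershed (vs a brute-force
oracle), boundary tracing and the contour overlay."""

import numpy as np
import pytest

from oracles import brute_force_flood, brute_force_relief
from ulcermetrics import (
    ScribbleSet,
    extract_boundary,
    overlay_contour,
    priority_flood,
    rasterize_scribbles,
    watershed_segment,
)
from ulcermetrics.errors import (
    EmptyMask,
    MissingMarker,
    MultipleComponents,
    OutOfBounds,
    OverlappingScribbles,
)
from ulcermetrics.pipeline import default_scribbles
from ulcermetrics.ulcer import gradient_relief


# ---------------------------------------------------------------- scribbles

def test_rasterize_row_stroke():
    s = ScribbleSet(skin_stroke=[(0, 0), (0, 2)], ulcer_stroke=[(4, 4)])
    grid = rasterize_scribbles(s, 5, 5)
    assert [tuple(p) for p in np.argwhere(grid == 1)] == [(0, 0), (0, 1), (0, 2)]
    assert [tuple(p) for p in np.argwhere(grid == 2)] == [(4, 4)]


def test_rasterize_single_points():
    grid = rasterize_scribbles(ScribbleSet([(1, 1)], [(3, 3)]), 5, 5)
    assert grid[1, 1] == 1 and grid[3, 3] == 2 and grid.sum() == 3


def test_rasterize_overlap_rejected():
    s = ScribbleSet(skin_stroke=[(2, 0), (2, 4)], ulcer_stroke=[(2, 2)])
    with pytest.raises(OverlappingScribbles):
        rasterize_scribbles(s, 5, 5)


def test_rasterize_out_of_bounds():
    with pytest.raises(OutOfBounds):
        rasterize_scribbles(ScribbleSet([(0, 0)], [(9, 0)]), 5, 5)


# ---------------------------------------------------------------- watershed

def test_flood_worked_row_example():
    """1x5 luminance row (200,200,80,80,80): the ulcer seed at col 4 floods
    left across the flat dark shelf and wins col 2; skin keeps cols 0-1."""
    lum = np.array([[200.0, 200.0, 80.0, 80.0, 80.0]])
    relief = gradient_relief(lum)
    assert relief.tolist() == [[0.0, 120.0, 120.0, 0.0, 0.0]]
    seeds = np.array([[1, 0, 0, 0, 2]], dtype=np.int32)
    labels = priority_flood(relief, seeds)
    assert labels.tolist() == [[1, 1, 2, 2, 2]]
    assert labels.tolist() == brute_force_flood(relief, seeds).tolist()


def test_flood_uniform_image_partitions():
    relief = np.zeros((9, 9))
    seeds = np.zeros((9, 9), dtype=np.int32)
    seeds[0, 0] = 1
    seeds[8, 8] = 2
    labels = priority_flood(relief, seeds)
    assert ((labels == 1) | (labels == 2)).all()
    assert labels.tolist() == brute_force_flood(relief, seeds).tolist()


def test_flood_matches_brute_force_on_random_grids(rng):
    """100 random 8x8 reliefs with random marker pairs: labelings identical
    to the literal scan-the-queue oracle."""
    for _ in range(100):
        lum = rng.integers(0, 256, size=(8, 8)).astype(float)
        relief = gradient_relief(lum)
        assert np.array_equal(relief, brute_force_relief(lum))
        seeds = np.zeros((8, 8), dtype=np.int32)
        n_skin, n_ulcer = rng.integers(1, 4, size=2)
        flat = rng.choice(64, size=int(n_skin + n_ulcer), replace=False)
        for i, f in enumerate(flat):
            seeds[f // 8, f % 8] = 1 if i < n_skin else 2
        assert np.array_equal(
            priority_flood(relief, seeds), brute_force_flood(relief, seeds)
        )


def test_marker_pixels_keep_labels(rng):
    lum = rng.integers(0, 256, size=(12, 12)).astype(float)
    seeds = np.zeros((12, 12), dtype=np.int32)
    seeds[2, 2] = 1
    seeds[9, 9] = 2
    labels = priority_flood(gradient_relief(lum), seeds)
    assert labels[2, 2] == 1 and labels[9, 9] == 2


def test_watershed_requires_both_markers(clean_scene):
    markers = np.zeros(clean_scene.image.shape[:2], dtype=np.int32)
    markers[0, 0] = 1
    with pytest.raises(MissingMarker):
        watershed_segment(clean_scene.image, markers, clean_scene.foot_mask)


def test_watershed_recovers_fixture_ulcer(clean_scene):
    scrib = default_scribbles(clean_scene)
    markers = rasterize_scribbles(scrib, *clean_scene.image.shape[:2])
    seg = watershed_segment(clean_scene.image, markers, clean_scene.foot_mask)
    inter = (seg.ulcer_mask & clean_scene.ulcer_mask).sum()
    union = (seg.ulcer_mask | clean_scene.ulcer_mask).sum()
    assert inter / union >= 0.90
    assert not (seg.ulcer_mask & ~clean_scene.foot_mask).any()


def test_watershed_scribble_jitter_robust(clean_scene, rng):
    """±2 px jitter on stroke points (strokes drawn 5 px clear of the true
    boundary, so jitter keeps them on the correct side) moves the measured
    pixel count by <= 5%."""
    scrib = default_scribbles(clean_scene)
    h, w = clean_scene.image.shape[:2]
    markers = rasterize_scribbles(scrib, h, w)
    base = watershed_segment(clean_scene.image, markers, clean_scene.foot_mask)
    jitter = lambda pts: [
        (int(np.clip(r + rng.integers(-2, 3), 0, h - 1)),
         int(np.clip(c + rng.integers(-2, 3), 0, w - 1)))
        for r, c in pts
    ]
    jittered = ScribbleSet(jitter(scrib.skin_stroke), jitter(scrib.ulcer_stroke))
    seg = watershed_segment(
        clean_scene.image, rasterize_scribbles(jittered, h, w), clean_scene.foot_mask
    )
    assert abs(seg.n_ulcer_px - base.n_ulcer_px) / base.n_ulcer_px <= 0.05


def test_watershed_foot_partition(clean_scene):
    scrib = default_scribbles(clean_scene)
    markers = rasterize_scribbles(scrib, *clean_scene.image.shape[:2])
    from ulcermetrics.ulcer import priority_flood as pf

    relief = gradient_relief(clean_scene.image)
    seeds = np.where(clean_scene.foot_mask, 0, 1).astype(np.int32)
    seeds[markers > 0] = markers[markers > 0]
    labels = pf(relief, seeds)
    assert (labels[clean_scene.foot_mask] > 0).all()


# ----------------------------------------------------------------- boundary

def test_boundary_single_pixel():
    mask = np.zeros((5, 5), bool)
    mask[2, 2] = True
    assert extract_boundary(mask) == [(2, 2), (2, 2)]


def test_boundary_2x2_block_clockwise():
    mask = np.zeros((4, 4), bool)
    mask[1:3, 1:3] = True
    assert extract_boundary(mask) == [(1, 1), (1, 2), (2, 2), (2, 1), (1, 1)]


def test_boundary_empty_and_split_masks():
    with pytest.raises(EmptyMask):
        extract_boundary(np.zeros((3, 3), bool))
    split = np.zeros((5, 5), bool)
    split[0, 0] = split[4, 4] = True
    with pytest.raises(MultipleComponents):
        extract_boundary(split)


def test_boundary_covers_disc_edge():
    rr, cc = np.mgrid[0:30, 0:30]
    mask = (rr - 15) ** 2 + (cc - 15) ** 2 <= 100
    contour = extract_boundary(mask)
    assert contour[0] == contour[-1]
    pts = set(contour)
    # every contour pixel is on the mask's 4-boundary
    for r, c in pts:
        assert mask[r, c]
    from scipy import ndimage

    interior = ndimage.binary_erosion(mask)
    boundary = mask & ~interior
    assert pts == {tuple(p) for p in np.argwhere(boundary)}


# ------------------------------------------------------------------ overlay

def test_overlay_paints_and_preserves(clean_scene):
    contour = [(0, 0), (1, 1), (2, 2)]
    out = overlay_contour(clean_scene.image, contour)
    assert not np.shares_memory(out, clean_scene.image)
    for r, c in contour:
        assert tuple(out[r, c]) == (0, 255, 0)
    diff = (out != clean_scene.image).any(axis=2).sum()
    assert diff <= len(contour)
    assert np.array_equal(overlay_contour(out, contour), out)  # idempotent


def test_overlay_empty_contour_is_copy(clean_scene):
    out = overlay_contour(clean_scene.image, [])
    assert np.array_equal(out, clean_scene.image)
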