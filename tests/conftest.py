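import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from ulcermetrics import SceneParams, generate_scene


@pytest.fixture
def clean_scene():
    """Default noise-free scene with 20 px sticker radius (40 px/cm)."""
    return generate_scene(SceneParams())


@pytest.fixture
def noisy_scene():
    return generate_scene(SceneParams(noise_sigma=10.0, seed=7))


@pytest.fixture
def square_ulcer_scene():
    """Axis-aligned 40x40 px square ulcer with a 20 px sticker: exactly
    1600 px = 1.0 cm² of wound."""
    verts = [(99.5, 79.5), (99.5, 119.5), (139.5, 119.5), (139.5, 79.5)]
    return generate_scene(SceneParams(ulcer_vertices_px=verts))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
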