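import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from colocquant import ROIMask, SceneParams, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def full_roi():
    def _make(shape):
        return ROIMask.full(shape)
    return _make


@pytest.fixture
def triple_scene():
    """A deterministic three-marker scene with half its puncta shared."""
    params = SceneParams(channels=("R", "G", "F"), coloc_fraction=0.5,
                         seed=7)
    scene, truth = generate_scene(params)
    return scene, truth
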