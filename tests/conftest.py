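import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

sys.path.insert(0, str(Path(__file__).parent))  # reference_impl

from equitherm import EffectModel, StudyDesign, generate_study


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture(scope="session")
def tiny_study():
    """2 horses x 3 REs at a small frame; full effect structure present."""
    design = StudyDesign(
        n_horses=2, n_re=3, image_height=48, image_width=64, seed=11
    )
    return generate_study(design, EffectModel())


@pytest.fixture(scope="session")
def full_mask():
    def make(h, w):
        return np.ones((h, w), dtype=bool)

    return make


def random_channel(rng, shape=(12, 12), n_levels=4):
    """Random gray plane at few levels, 1-based, as the matrix families use."""
    return rng.integers(1, n_levels + 1, size=shape).astype(np.int32)
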