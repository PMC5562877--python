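import numpy as np
import pytest

from forestcc.grid import GridSpec
from forestcc import scenegen


@pytest.fixture
def grid10():
    return GridSpec(rows=10, cols=10, year_start=2000, year_end=2013)


@pytest.fixture
def loss_scene(grid10):
    """Zero-noise landscape: stable forest/non-forest plus abrupt loss in 2006.

    Every event is pinned to 2006, inside both stable-map windows' gap, so
    all four rendered products imply the same parent-pixel change labels.
    """
    mix = {"stable_forest": 0.5, "stable_nonforest": 0.3, "abrupt_loss": 0.2}
    return scenegen.make_truth(grid10, mix, seed=11, event_year=2006)


@pytest.fixture
def loss_mask(loss_scene):
    return loss_scene.cover(2000) >= 0.5
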