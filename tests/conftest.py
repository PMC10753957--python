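import numpy as np
import pytest

from mitoscore import LabelVolume, build_fig4_scene


@pytest.fixture(scope="session")
def toy_scene():
    """The default six-instance toy scene: (gt, pred)."""
    return build_fig4_scene()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_label_pair(rng, shape=(8, 8, 8), max_gt=3, max_pred=4):
    """A pair of small random label grids (not necessarily contiguous)."""
    gt = LabelVolume(rng.integers(0, max_gt + 1, size=shape).astype(np.int64))
    pred = LabelVolume(rng.integers(0, max_pred + 1, size=shape).astype(np.int64))
    return gt, pred
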