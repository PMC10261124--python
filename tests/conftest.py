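import numpy as np
import pytest

from nucsplit3d import LabelVolume, SynthConfig, generate_labels


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_labels():
    """A deterministic ~10-nucleus label volume at 48^3."""
    cfg = SynthConfig(shape=(48, 48, 48), n_nuclei=10, a_min=4, a_max=8,
                      t_ov=5, grid=4, sigma=2.0)
    return generate_labels(cfg, np.random.default_rng(7))


@pytest.fixture
def cube_labels():
    """One 3x3x3 cube spanning [2..4]^3 in a 8^3 volume (centroid (3,3,3))."""
    data = np.zeros((8, 8, 8), dtype=np.int32)
    data[2:5, 2:5, 2:5] = 1
    return LabelVolume(data)
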