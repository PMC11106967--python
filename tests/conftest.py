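import numpy as np
import pytest

from rootct.volume_io import CTVolume, LabelVolume


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def gray8_volume(rng):
    data = rng.integers(0, 256, size=(12, 10, 11), dtype=np.uint8)
    return CTVolume(data, "gray8")


@pytest.fixture
def raw16_bimodal(rng):
    """Half air-like voxels around 1000, half soil-like around 20000."""
    n = 16 * 16 * 16
    air = rng.normal(1000, 20, n // 2)
    soil = rng.normal(20000, 200, n - n // 2)
    data = np.concatenate([air, soil])
    rng.shuffle(data)
    data = np.clip(np.round(data), 0, 65535).astype(np.uint16)
    return CTVolume(data.reshape(16, 16, 16), "raw16")


@pytest.fixture
def tube_volume():
    """A bright vertical tube of radius 2 in a uniform background."""
    data = np.full((16, 16, 16), 40, dtype=np.uint8)
    w = np.arange(16) - 8
    mask = (w[:, None] ** 2 + w[None, :] ** 2) <= 4
    data[:, mask] = 200
    return CTVolume(data, "gray8")


@pytest.fixture
def label_pair(rng):
    pred = LabelVolume(rng.random((6, 7, 8)) > 0.6)
    truth = LabelVolume(rng.random((6, 7, 8)) > 0.6)
    return pred, truth
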