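import numpy as np
import pytest

from hsidrought.simulate import SimParams


@pytest.fixture(scope="session")
def small_params() -> SimParams:
    """Desk-scale simulator settings: 128 bands, 32x32 frame."""
    return SimParams(n_bands=128, frame_size=(32, 32), leaf_shape=(18, 12), seed=0)


@pytest.fixture(scope="session")
def tiny_params() -> SimParams:
    """Minimal cubes for dataset-level arithmetic tests."""
    return SimParams(n_bands=16, frame_size=(16, 16), leaf_shape=(8, 6),
                     pixel_noise_sd=0.005, seed=0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
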