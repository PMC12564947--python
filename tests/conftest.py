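import numpy as np
import pytest

from boluseg.phantom import AnomalySpec, PhantomSpec, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_spec():
    return PhantomSpec(height=32, width=32, n_blobs=4, noise_sigma=0.05, jitter_px=1, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    anomaly = AnomalySpec(semi_axes=(4, 3), mode="additive", delta=0.4)
    return generate_dataset(small_spec, anomaly, n_train=12, n_test_clean=3, n_test_anom=5, seed=7)


class IdentityModel:
    """Stand-in model whose reconstruction equals the input image channels.

    Lets segmentation plumbing be tested independently of training.
    """

    def __init__(self, in_channels=5, out_channels=3, offset=0.0):
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.offset = offset

    def predict(self, x, batch_size=16):
        return np.clip(x[..., : self.out_channels] + self.offset, None, None)


@pytest.fixture
def identity_model():
    return IdentityModel()
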