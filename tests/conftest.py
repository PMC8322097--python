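import numpy as np
import pytest

from scampi import GrayscaleImage, LagSimSpec, simulate_lag_image

OKT3_BETA = (0.6443, 0.6674, -0.3438)
PLL_BETA = (0.5671, 0.5943, -0.1992)
OKT3_SD = (0.0314, 0.0316, 0.0541)
PLL_SD = (0.0612, 0.0613, 0.1043)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_image():
    """3x3 image with pixels[i, j] = 3i + j + 1 (values 1..9)."""
    return GrayscaleImage(np.arange(1, 10, dtype=float).reshape(3, 3))


@pytest.fixture
def lag_image():
    """Moderate-noise one-lag simulated image with known coefficients."""
    spec = LagSimSpec(
        shape=(128, 128),
        beta=(0.6, 0.3, 0.05),
        innovation_sd=3.0,
        boundary_mean=50.0,
        boundary_sd=3.0,
        seed=42,
    )
    return simulate_lag_image(spec), spec


def gaussian_cloud(rng, mean, sd, n):
    """n parameter rows drawn iid normal per coordinate."""
    return rng.normal(np.asarray(mean), np.asarray(sd), size=(n, len(mean)))
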