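import numpy as np
import pytest

from ventmap.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """Structured 32³ phantom with default noise (fast, for unit tests)."""
    spec = PhantomSpec.default(grid_shape=(32, 32, 32), seed=11)
    return spec, generate_phantom(spec)


@pytest.fixture(scope="session")
def noisefree_phantom():
    """Noise-free structured 32³ phantom (identity checks)."""
    spec = PhantomSpec.default(grid_shape=(32, 32, 32), seed=11)
    spec.hu_noise_sd = 0.0
    spec.exp_noise_sd = 0.0
    spec.progression.density_noise_sd = 0.0
    return spec, generate_phantom(spec)


@pytest.fixture(scope="session")
def ramp_image():
    from ventmap.image import VolumetricImage

    data = np.arange(16**3, dtype=float).reshape(16, 16, 16)
    return VolumetricImage(data, spacing=(1.0, 1.0, 1.0))
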