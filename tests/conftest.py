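import numpy as np
import pytest

from fatnav.synthetic import PhantomSpec, default_phantom_specs, generate_phantom


@pytest.fixture(scope="session")
def shell_phantom():
    """Smooth navigator-like shell phantom, 2 mm isotropic, 64x64x44."""
    return generate_phantom(default_phantom_specs(1, seed=7)[0])


@pytest.fixture(scope="session")
def small_phantom():
    """Small smooth phantom for fast tests."""
    return generate_phantom(default_phantom_specs(1, shape=(32, 32, 24), seed=3)[0])


@pytest.fixture(scope="session")
def hard_shell_spec():
    """Noiseless, unsmoothed shell spec with exactly-known intensities."""
    return PhantomSpec(shape=(32, 32, 24), noise_sd=0.0, smooth_sigma_mm=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
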