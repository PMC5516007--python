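import numpy as np
import pytest

from iconet import (
    PhantomSpec,
    make_phantom_slice,
    make_tilt_scheme,
    simulate_sinogram,
)


@pytest.fixture(scope="session")
def wedge_scheme():
    """±60° wedge, 2° steps — the every-other-projection acquisition."""
    return make_tilt_scheme(-60, 60, 2)


@pytest.fixture(scope="session")
def wedge_case_64(wedge_scheme):
    """Seeded 64×64 phantom and its noiseless ±60° sinogram."""
    phantom = make_phantom_slice(PhantomSpec(N=64, n_blobs=8, seed=0))
    sinogram = simulate_sinogram(phantom, wedge_scheme)
    return phantom, sinogram, wedge_scheme


@pytest.fixture(scope="session")
def small_case_32():
    """32×32 phantom with a moderate wedge, for fast reconstruction tests."""
    scheme = make_tilt_scheme(-60, 60, 4)
    phantom = make_phantom_slice(PhantomSpec(N=32, n_blobs=5, seed=1))
    sinogram = simulate_sinogram(phantom, scheme)
    return phantom, sinogram, scheme


@pytest.fixture
def rng():
    return np.random.default_rng(0)
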