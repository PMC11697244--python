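import numpy as np
import pytest

from dspa import (
    FitConfig,
    GridSpec,
    SweepConfig,
    acquire_sweep,
    polarization_spectrum,
    tendon_presets,
)


@pytest.fixture(scope="session")
def small_grid():
    """Narrow grid (8 columns) for speed; same depth sampling as the default."""
    return GridSpec(n_depth=36, n_lateral=8, dz=0.01, dx=0.05)


@pytest.fixture(scope="session")
def single_phantom(small_grid):
    return tendon_presets("single", phi1=30.0, grid=small_grid)


@pytest.fixture(scope="session")
def noiseless_stack(single_phantom):
    return acquire_sweep(single_phantom)


@pytest.fixture(scope="session")
def noiseless_spectral(noiseless_stack):
    return polarization_spectrum(noiseless_stack)


@pytest.fixture()
def noiseless_fit_cfg():
    # explicit (numerically zero) background sigma: nothing gets masked
    return FitConfig(noise_sigma_source=1e-12)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(42)
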