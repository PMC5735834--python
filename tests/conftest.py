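import numpy as np
import pytest

from cinedenoise import PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def small_config() -> PhantomConfig:
    """A coarse phantom (24 mm FOV at 0.5 mm) small enough for filter tests."""
    return PhantomConfig(
        nx=48, ny=48, n_slices=6, n_phases=8,
        dx=0.5, dy=0.5, dz=1.0,
        r_ed=4.5, r_es=2.8, myo_volume=300.0,
        base_slice=1, apex_slice=4,
    )


@pytest.fixture(scope="session")
def small_phantom(small_config):
    return generate_phantom(small_config)


@pytest.fixture(scope="session")
def noisy_cube():
    """A 16^3 positive noisy volume for solver-oracle comparisons."""
    rng = np.random.default_rng(7)
    return np.abs(rng.normal(5.0, 1.0, (16, 16, 16)))
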