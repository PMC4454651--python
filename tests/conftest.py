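import numpy as np
import pytest

from lymphir import PhantomSpec, SpectralCube, WavenumberAxis, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def axis8():
    """Tiny 8-band axis: 1000..1028 step 4."""
    return WavenumberAxis.from_range(1000.0, 1028.0, 4.0)


@pytest.fixture
def random_cube(rng, axis8):
    return SpectralCube(rng.normal(0.5, 0.1, size=(4, 5, 8)), axis8, 1.1)


@pytest.fixture(scope="session")
def small_follicle():
    """One 64x64 follicle phantom shared across tests (read-only)."""
    spec = PhantomSpec(rows=64, cols=64, seed=11)
    return generate_phantom(spec)
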