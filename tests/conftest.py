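import numpy as np
import pytest

from scapseg import phantom as ph


@pytest.fixture(scope="session")
def default_phantom():
    """One default-geometry phantom at 0.5 mm isotropic resolution."""
    spec = ph.PhantomSpec()
    mask, truth = ph.generate_phantom(spec)
    return mask, truth


@pytest.fixture(scope="session")
def small_phantom():
    """A 64-cube phantom (anisotropic spacing) with a rendered volume."""
    spec = ph.PhantomSpec(shape=(64, 64, 64), spacing=(1.5, 0.75, 1.375))
    mask, truth = ph.generate_phantom(spec)
    vol = ph.render_intensity(mask, seed=5)
    return vol, mask, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
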