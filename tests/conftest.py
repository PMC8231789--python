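import hypothesis
import numpy as np
import pytest

from tumorbedreg.phantoms import PhantomConfig, generate_pair
from tumorbedreg.volumes_io import Image3D

hypothesis.settings.register_profile(
    "deterministic", deadline=None, derandomize=True)
hypothesis.settings.load_profile("deterministic")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def phantom_small():
    """One 32-cubed resection phantom, shared across tests (read-only)."""
    return generate_pair(PhantomConfig(shape=(32, 32, 32)), seed=1)


@pytest.fixture(scope="session")
def phantom_undeformed():
    """Phantom with zero deformation and zero noise (degenerate config)."""
    cfg = PhantomConfig(shape=(32, 32, 32),
                        deformation_amplitude_mm=(0.0, 0.0), noise_sigma=0.0)
    return generate_pair(cfg, seed=3)


@pytest.fixture()
def smooth_volume(rng):
    """A smooth random 16-cubed volume at 2 mm spacing."""
    from scipy.ndimage import gaussian_filter
    data = gaussian_filter(rng.random((16, 16, 16)), sigma=2.0)
    data = (data - data.min()) / (data.max() - data.min())
    return Image3D(data, np.full(3, 2.0), np.zeros(3))
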