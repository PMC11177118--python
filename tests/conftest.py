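import numpy as np
import pytest
from hypothesis import settings

from flimviab import AcquisitionConfig
from flimviab.simulate import make_irf

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("ci")


@pytest.fixture()
def acq() -> AcquisitionConfig:
    """Small acquisition used throughout: 64 bins, 12.5 ns period."""
    return AcquisitionConfig(n_time_bins=64, image_size=64, seed=0)


@pytest.fixture()
def acq_fine() -> AcquisitionConfig:
    """Full 256-bin acquisition for closed-form phasor checks."""
    return AcquisitionConfig(n_time_bins=256, image_size=64, seed=0)


@pytest.fixture()
def irf_hist(acq):
    """Noiseless single-pixel IRF histogram for the small acquisition."""
    return make_irf(acq, 1e6).counts[:, 0, 0]


@pytest.fixture()
def irf_hist_fine(acq_fine):
    return make_irf(acq_fine, 1e6).counts[:, 0, 0]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
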