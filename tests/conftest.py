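import numpy as np
import pytest

from flimfret import AcquisitionConfig, IrfModel


@pytest.fixture
def acq() -> AcquisitionConfig:
    """Default 20 MHz / 1024-channel acquisition."""
    return AcquisitionConfig(seed=0)


@pytest.fixture
def small_acq() -> AcquisitionConfig:
    """Coarse 256-channel acquisition for cheap fits."""
    return AcquisitionConfig(n_channels=256, channel_width=50.0 / 256.0, seed=0)


@pytest.fixture
def irf() -> IrfModel:
    return IrfModel(center=2.0, fwhm=0.1)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
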