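import numpy as np
import pytest

from vhlift.models import SineLiftParams
from vhlift.synthetic import LiftSimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def base_params():
    """200-g cube (weight 1.962 N), 0.4-s loading phase."""
    return SineLiftParams(m=1.962, d=0.4, onset=0.0)


@pytest.fixture
def quiet_cfg():
    """Noiseless default lift configuration."""
    return LiftSimConfig(noise_sd=0.0)


@pytest.fixture
def times():
    """500-Hz time base covering a full loading phase and plateau."""
    return np.arange(0.0, 1.5, 0.002)
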