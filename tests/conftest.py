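import numpy as np
import pytest

from burstlab import WT_PARAMS, standard_spot_field


@pytest.fixture(scope="session")
def wt_params():
    return WT_PARAMS


@pytest.fixture(scope="session")
def spot_field():
    """Standard synthetic detection fixture: SNR 10, sparse well-spread spots."""
    image, truth, mask = standard_spot_field(seed=42, snr=10.0)
    return image, truth, mask


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
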