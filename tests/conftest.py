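import numpy as np
import pytest

from swinbeat.io import beats_to_array
from swinbeat.synthetic import SyntheticConfig, generate_beats


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_beats():
    """20 beats per class at 15 dB SNR, fixed seed."""
    cfg = SyntheticConfig(n_per_class=20, snr_db=15.0, seed=1)
    return generate_beats(cfg)


@pytest.fixture(scope="session")
def small_Xy(small_beats):
    return beats_to_array(small_beats)
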