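import warnings

import numpy as np
import pytest

from seascord import SyntheticSpec, generate_series

from helpers import make_series

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def constant_series():
    return make_series(np.full(48, 5.0))


@pytest.fixture
def random_series(rng):
    """48-month eligible series of positive white noise around 5 per-thousand."""
    return make_series(np.maximum(0.0, 5.0 + rng.normal(0, 0.3, 48)))


@pytest.fixture
def harmonic_series():
    """Spiky seasonal series (strong-harmonic regime), deterministic seed."""
    return generate_series(
        SyntheticSpec(
            years=6,
            baseline=5.0,
            amplitude=2.0,
            peak_month=2,
            peak_sharpness=3.0,
            noise_sd=0.2,
            trend_slope=0.01,
            seed=7,
        )
    )


@pytest.fixture
def cosine_series():
    """Noiseless pure-cosine series over 8 years."""
    t = np.arange(96)
    values = 5.0 + 2.0 * np.cos(2 * np.pi * (t % 12) / 12.0)
    return make_series(values)
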