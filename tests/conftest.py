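import numpy as np
import pytest

from rsathresh.histograms import ChannelHistogram
from rsathresh.synthetic import MixtureSpec, gaussian_mixture_image, ramp_image


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def uniform_hist():
    """Exactly uniform 256-level histogram (4 counts per level)."""
    return ChannelHistogram(np.full(256, 4))


@pytest.fixture
def two_delta_hist():
    """All mass split evenly between levels 0 and 255."""
    counts = np.zeros(256, dtype=int)
    counts[0] = counts[255] = 50
    return ChannelHistogram(counts)


@pytest.fixture
def bimodal_image():
    spec = MixtureSpec(((64, 5, 0.5), (192, 5, 0.5)), (64, 64), seed=7)
    return gaussian_mixture_image(spec)


@pytest.fixture
def ramp():
    return ramp_image((4, 256))


def random_histogram(rng, n_levels_support=256, total=5000):
    """Random histogram with mass on the first ``n_levels_support`` levels."""
    counts = np.zeros(256, dtype=int)
    counts[:n_levels_support] = rng.integers(0, 40, size=n_levels_support)
    if counts.sum() == 0:
        counts[0] = 1
    return ChannelHistogram(counts)
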