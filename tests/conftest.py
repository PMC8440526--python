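import numpy as np
import pytest

from idrfret.flim import DecayHistogram, decay_shape


def noiseless_decay(tau, rep_period=25.0, n_bins=256, amplitude=1e4, background=0.0):
    """Exact (un-sampled) mono-exponential histogram for fit/phasor tests."""
    dt = rep_period / n_bins
    centers = (np.arange(n_bins) + 0.5) * dt
    counts = amplitude * decay_shape(centers, tau, rep_period) + background
    return DecayHistogram(bin_centers=centers, counts=counts, rep_period=rep_period)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
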