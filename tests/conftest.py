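import numpy as np
import pytest

from retphen.simulate import ErgTruth, simulate_series


@pytest.fixture(scope="session")
def default_truth():
    return ErgTruth()


@pytest.fixture(scope="session")
def noiseless_series(default_truth):
    """One clean luminance series at the default stimulus ladder."""
    return simulate_series(default_truth, seed_or_rng=1, noise_sd=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
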