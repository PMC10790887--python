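import pytest

from p300kit import build_default_encoder
from p300kit.simulator import SimConfig, synthesize


@pytest.fixture(scope="session")
def encoder():
    return build_default_encoder()


@pytest.fixture(scope="session")
def small_rec():
    """A short noisy session: 3 characters x 5 iterations."""
    return synthesize(SimConfig(text="FOX", iterations=5, seed=42, noise_sd=2.0))


@pytest.fixture(scope="session")
def clean_rec():
    """A noiseless session for exact-separability checks."""
    return synthesize(SimConfig(text="WXYZ", iterations=3, seed=7, noise_sd=0.0))
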