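import numpy as np
import pytest

from laseg.segnet import NetworkConfig, SegSeqNet
from laseg.synthetic_data import PhantomConfig, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def default_phantom():
    """One phantom at the generator's default conditions."""
    return generate_phantom(PhantomConfig(seed=7))


@pytest.fixture(scope="session")
def small_phantom():
    """A small, quick phantom for I/O and pipeline tests."""
    return generate_phantom(PhantomConfig(n_slices=8, height=32, width=32,
                                          seed=3))


@pytest.fixture(scope="session")
def tiny_net_config():
    """Smallest practical network for fast forward/backward tests."""
    return NetworkConfig.reduced(16, seq_len=2, msa_max_grid=8)


@pytest.fixture(scope="session")
def tiny_model(tiny_net_config):
    return SegSeqNet(tiny_net_config, seed=0)
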