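import numpy as np
import pytest

from snnevo import build_network, decode_genome
from snnevo.experiment import ProtocolConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def micro_protocol():
    return ProtocolConfig.micro()


@pytest.fixture
def small_net():
    """A grid-8 network from a mid/high genome, deterministic build."""
    genome = np.full(14, 0.8)
    params = decode_genome(genome)
    return build_network(8, params, np.random.default_rng(7))
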