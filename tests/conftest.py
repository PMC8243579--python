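import numpy as np
import pytest

from iegkin.synthetic import NOISELESS, NoiseModel, SamplingProtocol


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def is1():
    return SamplingProtocol.is1()


@pytest.fixture
def is2():
    return SamplingProtocol.is2()


@pytest.fixture
def noiseless():
    return NOISELESS


@pytest.fixture
def noise5():
    """The default study noise: 5% multiplicative plus a small additive floor."""
    return NoiseModel(scale=0.05, floor_du=2.0)
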