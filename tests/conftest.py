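import numpy as np
import pytest

from ternadock.synthetic import ToyComplexSpec, make_toy_complex


@pytest.fixture(scope="session")
def toy():
    """One deterministic toy ternary complex shared across tests."""
    return make_toy_complex(ToyComplexSpec(seed=1))


@pytest.fixture(scope="session")
def toy_pair():
    """Two distinct toy complexes."""
    return (make_toy_complex(ToyComplexSpec(seed=2)),
            make_toy_complex(ToyComplexSpec(seed=3)))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
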