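import numpy as np
import pytest

from genepower.genotypes import make_realistic_fixture


@pytest.fixture(scope="session")
def realistic_pool():
    return make_realistic_fixture(seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
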