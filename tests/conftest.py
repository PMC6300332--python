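import numpy as np
import pytest

from netsurv import (
    CommunityStructure,
    NetworkSequence,
    build_block_matrix,
    make_fixture,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20181219)


@pytest.fixture
def two_communities():
    return CommunityStructure((10, 10))


@pytest.fixture
def block_2to1():
    return build_block_matrix(1.0, 2.0, 2)


@pytest.fixture
def triangle():
    return make_fixture("triangle")


@pytest.fixture
def constant_sequence():
    return make_fixture("constant-sequence")


def random_count_sequence(rng, T=10, n=6, lam=1.0):
    """Small random symmetric count sequence for structural tests."""
    iu, ju = np.triu_indices(n, k=1)
    data = np.zeros((T, n, n), dtype=np.int64)
    counts = rng.poisson(lam, size=(T, iu.size))
    data[:, iu, ju] = counts
    data[:, ju, iu] = counts
    return NetworkSequence(data=data)
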