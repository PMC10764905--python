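import numpy as np
import pytest

from overnet import (
    BinaryGraph,
    LFRParams,
    MembershipMatrix,
    generate_hierarchical_dataset,
    generate_lfr_graph,
)


@pytest.fixture(scope="session")
def two_cliques() -> BinaryGraph:
    """Two disjoint 20-node cliques: the simplest planted 2-partition."""
    a = np.zeros((40, 40), dtype=int)
    a[:20, :20] = 1
    a[20:, 20:] = 1
    np.fill_diagonal(a, 0)
    return BinaryGraph(a)


@pytest.fixture(scope="session")
def lfr_disjoint_small():
    """A small disjoint LFR-style benchmark (no overlapping nodes)."""
    params = LFRParams(N=120, k=15, mu_topo=0.1, c_min=20, c_max=40, ON=0)
    return generate_lfr_graph(params, seed=7)


@pytest.fixture(scope="session")
def two_block_truth() -> MembershipMatrix:
    pi = np.zeros((40, 2))
    pi[:20, 0] = 1.0
    pi[20:, 1] = 1.0
    return MembershipMatrix(pi)


@pytest.fixture()
def small_dataset(two_block_truth):
    return generate_hierarchical_dataset(
        2, 2, 2, 40, 300, two_block_truth, noise_sd=0.1, fs=1.0, seed=3
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
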