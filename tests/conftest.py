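import numpy as np
import pytest

from sibnet import EnsembleConfig, SignedNetwork, decompose, load_fixture, sample_network

#: the seven fixed points of the budding-yeast cell-cycle network under the
#: strong-inhibition update (node 1 leftmost)
YEAST_ATTRACTORS = {
    "00001000100",
    "01001000100",
    "01000000100",
    "00000000100",
    "00001000000",
    "00110000000",
    "00000000000",
}

YEAST_PREIMAGES_OF_MAIN = {"00001100100", "00001000100", "00001100000"}


@pytest.fixture(scope="session")
def yeast():
    return load_fixture("budding_yeast").network


@pytest.fixture(scope="session")
def yeast_dec(yeast):
    return decompose(yeast)


@pytest.fixture
def mutual_inhibition():
    """Two nodes, each inhibiting the other."""
    return SignedNetwork(a=np.array([[0, -1], [-1, 0]]))


@pytest.fixture
def empty_net():
    def make(n):
        return SignedNetwork(a=np.zeros((n, n), dtype=int))

    return make


def random_networks(seed, count, n_range=(4, 12), k_choices=(1, 2, 3, 5), r_choices=(0.2, 0.4, 0.8)):
    """Reproducible stream of small random signed networks for oracle tests."""
    rng = np.random.default_rng(seed)
    for _ in range(count):
        n = int(rng.integers(n_range[0], n_range[1] + 1))
        k = float(rng.choice(k_choices))
        k = min(k, float(n))
        r = float(rng.choice(r_choices))
        cfg = EnsembleConfig(n_nodes=n, k_avg=k, r=r, seed=int(rng.integers(1 << 30)))
        yield sample_network(cfg, 0), rng
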