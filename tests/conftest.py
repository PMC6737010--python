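import numpy as np
import pytest

from connseg.atlas import NetworkPartition, load_bundled_atlas, select_networks
from connseg.connectivity import ConnectivityMatrix


@pytest.fixture(scope="session")
def bundled_atlas():
    return load_bundled_atlas()


@pytest.fixture(scope="session")
def default_partition(bundled_atlas):
    return select_networks(bundled_atlas)


def make_conn(z, mask=None, node_ids=None):
    """Build a ConnectivityMatrix with diagonal masked by default."""
    z = np.asarray(z, dtype=float)
    n = z.shape[0]
    if mask is None:
        mask = np.eye(n, dtype=bool)
    if node_ids is None:
        node_ids = np.arange(1, n + 1)
    return ConnectivityMatrix(z=z, mask=np.asarray(mask, bool),
                              node_ids=node_ids)


@pytest.fixture
def toy_ab_partition():
    """Two 2-node networks over nodes 1..4 (uses real network names)."""
    return NetworkPartition(
        assignment={1: "Hand", 2: "Hand", 3: "Vis", 4: "Vis"},
        selected_networks=("Hand", "Vis"),
        sizes={"Hand": 2, "Vis": 2},
    )


@pytest.fixture
def toy_ab_matrix():
    """z(1,2)=0.4, z(3,4)=0.2, all cross-network z=0.1."""
    z = np.full((4, 4), 0.1)
    z[0, 1] = z[1, 0] = 0.4
    z[2, 3] = z[3, 2] = 0.2
    np.fill_diagonal(z, 0.0)
    return make_conn(z)


def random_connectivity(rng, n, neg_frac=0.3):
    """Random symmetric z matrix with some negative cells, diag masked."""
    z = rng.normal(0.2, 0.3, size=(n, n))
    z[rng.random((n, n)) < neg_frac] *= -1
    z = (z + z.T) / 2
    np.fill_diagonal(z, 0.0)
    return make_conn(z)
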