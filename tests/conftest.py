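import numpy as np
import pytest

import mdmc
from mdmc.graph_io import Network, build_transition_model


def random_undirected_network(
    n_nodes: int = 20, p: float = 0.3, seed: int = 0, multigraph: bool = False
) -> Network:
    """Connected random undirected network without dangling nodes."""
    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(n_nodes, k=1)
    if multigraph:
        w = rng.poisson(p * 1.5, iu.size).astype(float)
        keep = w > 0
        net = Network.from_arrays(iu[keep], ju[keep], w[keep], n_nodes=n_nodes)
    else:
        keep = rng.random(iu.size) < p
        net = Network.from_arrays(iu[keep], ju[keep], n_nodes=n_nodes)
    deg = np.bincount(net.links_from, weights=net.weights, minlength=n_nodes)
    if (deg == 0).any():
        return random_undirected_network(n_nodes, p, seed + 1000, multigraph)
    return net


@pytest.fixture(scope="session")
def karate_model():
    net = mdmc.karate_club_network()
    return build_transition_model(net)


@pytest.fixture(scope="session")
def small_model():
    return build_transition_model(random_undirected_network(seed=3))


@pytest.fixture
def triangle_file(tmp_path):
    path = tmp_path / "triangle.tsv"
    path.write_text("1 2\n2 3\n3 1\n")
    return path
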