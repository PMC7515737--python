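import networkx as nx
import numpy as np
import pytest

import corewalk as cw


def random_connected_graph(n_nodes: int, rng_seed: int, m: int = 2) -> nx.Graph:
    """Connected preferential-attachment graph with string node labels."""
    g = nx.barabasi_albert_graph(n_nodes, m, seed=rng_seed)
    return nx.relabel_nodes(g, {i: f"n{i:04d}" for i in g.nodes()})


def brute_force_cores(g: nx.Graph) -> dict:
    """Independent oracle: largest k such that the node survives iterative
    removal of all nodes with degree < k (the maximal min-degree-k subgraph)."""
    cores = {}
    for v in g.nodes():
        best = 0
        for k in range(1, g.number_of_nodes() + 1):
            h = g.copy()
            while True:
                low = [u for u in h.nodes() if h.degree(u) < k]
                if not low:
                    break
                h.remove_nodes_from(low)
            if v in h:
                best = k
            else:
                break
        cores[v] = best
    return cores


@pytest.fixture(scope="session")
def small_fixture():
    """300-node synthetic network with one planted 40-node community."""
    return cw.generate_synthetic_fixture(
        n_nodes=300, attach_m=2, planted_sizes=(40,), planted_density=0.12,
        rng_seed=11,
    )


@pytest.fixture(scope="session")
def small_propagated(small_fixture):
    """Observed core-normalized propagation on the small fixture."""
    net, weights, seeds = small_fixture
    metrics = cw.k_shell_decomposition(net)
    W = cw.normalize_adjacency(net, metrics, "core")
    p0 = cw.weights_to_vector(W.nodes, weights)
    observed = cw.rwr_closed_form(W, p0)
    return net, metrics, W, p0, observed, seeds


def make_result(nodes, weights, pvalues) -> cw.PropagationResult:
    """PropagationResult built directly from arrays (for module tests)."""
    return cw.PropagationResult(
        nodes=tuple(nodes),
        weights=np.asarray(weights, dtype=float),
        pvalues=np.asarray(pvalues, dtype=float),
        n_networks=100,
    )
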