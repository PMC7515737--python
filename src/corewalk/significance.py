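"""Permutation significance of propagated weights.

Observed propagated weights are calibrated against an ensemble of random
degree-preserving networks (RDPN): the input network is rewired by double-
edge swaps — replace edges (u,v),(x,y) by (u,x),(v,y) — which preserve every
node's degree.  A swap is kept only if the rewired network stays connected;
otherwise it is rolled back.  Propagating the same input weights on each
random network yields, per node v, null weights w_1(v)..w_n(v), and the
empirical p-value

    p_v = (|{i : w_i(v) >= w(v)}| + 1) / (n + 1)

with the +1 smoothing that makes 1/(n+1) the smallest achievable value
(0.0099 at the default n = 100 networks).

Because a swap preserves degrees but not cores, node cores are recomputed
for every random network before core-based normalization.
"""

from __future__ import annotations

import hashlib
import json
import logging
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .graph_core import NodeMetrics, k_shell_decomposition
from .propagation import PropagationConfig, normalize_adjacency, rwr_closed_form

logger = logging.getLogger("corewalk")

__all__ = [
    "PropagationResult",
    "generate_rdpn",
    "ensemble_seed",
    "propagate_on_network",
    "propagate_ensemble",
    "empirical_pvalues",
    "network_hash",
    "load_or_generate_ensemble",
]

_CHUNK = 4096  # random numbers drawn per batch in the swap loop


def _bfs_reaches(adj: dict, source, target) -> bool:
    """Bidirectional breadth-first search; adj maps node -> set of nodes."""
    if source == target or target in adj[source]:
        return True
    front_a = {source}
    front_b = {target}
    seen_a = {source}
    seen_b = {target}
    while front_a and front_b:
        if len(front_a) > len(front_b):  # expand the smaller frontier
            front_a, front_b = front_b, front_a
            seen_a, seen_b = seen_b, seen_a
        next_front = set()
        for node in front_a:
            for nbr in adj[node]:
                if nbr in seen_b:
                    return True
                if nbr not in seen_a:
                    seen_a.add(nbr)
                    next_front.add(nbr)
        front_a = next_front
    return False


def generate_rdpn(
    net: nx.Graph, swap_factor: int = 100, rng_seed: int = 0
) -> nx.Graph:
    """One random degree-preserving connected rewiring of *net*.

    Attempts ``swap_factor * |edges|`` double-edge swaps.  A candidate swap
    is rejected when it would create a self-loop or an existing edge; an
    applied swap is rolled back if it disconnects the network.  Degree
    sequence and connectivity of the output are therefore identical to the
    input's.  Graphs too small or rigid to swap (acceptance rate < 1%) are
    returned best-effort with a warning.
    """
    if swap_factor < 1:
        raise ValueError("swap_factor must be >= 1")
    if not nx.is_connected(net):
        raise ValueError("RDPN generation requires a connected network")
    m = net.number_of_edges()
    if net.number_of_nodes() < 4 or m < 2:
        logger.warning("network too small to swap; returning a copy")
        return net.copy()
    rng = np.random.default_rng(rng_seed)
    edges = [tuple(e) for e in net.edges()]
    adj: dict = {v: set(net.neighbors(v)) for v in net.nodes()}
    attempts = swap_factor * m
    accepted = 0
    done = 0
    while done < attempts:
        batch = min(_CHUNK, attempts - done)
        idx = rng.integers(0, m, size=(batch, 2))
        flips = rng.integers(0, 2, size=(batch, 2)).astype(bool)
        for (i, j), (fi, fj) in zip(idx, flips):
            done += 1
            if i == j:
                continue
            u, v = edges[i]
            if fi:
                u, v = v, u
            x, y = edges[j]
            if fj:
                x, y = y, x
            if len({u, v, x, y}) < 4:
                continue
            if x in adj[u] or y in adj[v]:
                continue
            # apply swap: remove (u,v),(x,y); add (u,x),(v,y)
            adj[u].remove(v)
            adj[v].remove(u)
            adj[x].remove(y)
            adj[y].remove(x)
            adj[u].add(x)
            adj[x].add(u)
            adj[v].add(y)
            adj[y].add(v)
            # connectivity can only break between u's side and v's side:
            # every node stays attached to one of {u,v,x,y}, and u~x, v~y
            # via the new edges, so the graph is connected iff u reaches v.
            if _bfs_reaches(adj, u, v):
                edges[i] = (u, x)
                edges[j] = (v, y)
                accepted += 1
            else:  # rollback
                adj[u].discard(x)
                adj[x].discard(u)
                adj[v].discard(y)
                adj[y].discard(v)
                adj[u].add(v)
                adj[v].add(u)
                adj[x].add(y)
                adj[y].add(x)
    rate = accepted / attempts
    logger.info(
        "RDPN: %d/%d swaps accepted (%.1f%%)", accepted, attempts, 100 * rate
    )
    if rate < 0.01:
        logger.warning(
            "swap acceptance rate %.2f%% < 1%%; network is rigid, "
            "returning best-effort rewiring",
            100 * rate,
        )
    random_net: nx.Graph = nx.Graph()
    random_net.add_nodes_from(net.nodes())
    random_net.add_edges_from(edges)
    return random_net


def ensemble_seed(master_seed: int, network_index: int) -> int:
    """Deterministic per-network RNG seed, independent of worker count."""
    seq = np.random.SeedSequence(master_seed, spawn_key=(network_index,))
    return int(seq.generate_state(1)[0] % (2**31))


def propagate_on_network(
    net: nx.Graph,
    p0: np.ndarray,
    scheme: str,
    cfg: PropagationConfig | None = None,
    metrics: NodeMetrics | None = None,
) -> np.ndarray:
    """Normalize *net* under *scheme* and propagate *p0* (closed form).

    ``p0`` is aligned to the sorted node ordering of *net*.  Cores are
    computed from *net* itself unless precomputed metrics are given.
    """
    if metrics is None:
        metrics = k_shell_decomposition(net)
    W = normalize_adjacency(net, metrics, scheme)
    return rwr_closed_form(W, p0, cfg)


def _ensemble_worker(args) -> np.ndarray:
    edge_list, nodes, p0, scheme, cfg, seed, swap_factor = args
    net: nx.Graph = nx.Graph()
    net.add_nodes_from(nodes)
    net.add_edges_from(edge_list)
    random_net = generate_rdpn(net, swap_factor=swap_factor, rng_seed=seed)
    return propagate_on_network(random_net, p0, scheme, cfg)


def propagate_ensemble(
    net: nx.Graph,
    p0: np.ndarray,
    scheme: str,
    cfg: PropagationConfig | None = None,
    n_networks: int = 100,
    swap_factor: int = 100,
    master_seed: int = 0,
    workers: int = 1,
    random_nets: list[nx.Graph] | None = None,
) -> np.ndarray:
    """Null propagated weights: one row per random network.

    Each network's RNG stream derives from ``(master_seed, index)`` so the
    ensemble is identical at any worker count.  Pre-generated networks
    (e.g. from a cache) may be supplied via *random_nets*, in which case
    only the propagation step runs.
    """
    if random_nets is not None:
        rows = [
            propagate_on_network(rn, p0, scheme, cfg) for rn in random_nets
        ]
        return np.vstack(rows)
    seeds = [ensemble_seed(master_seed, i) for i in range(n_networks)]
    if workers > 1:
        edge_list = list(net.edges())
        nodes = list(net.nodes())
        jobs = [
            (edge_list, nodes, p0, scheme, cfg, s, swap_factor) for s in seeds
        ]
        with ProcessPoolExecutor(max_workers=workers) as pool:
            rows = list(pool.map(_ensemble_worker, jobs))
    else:
        rows = []
        for s in seeds:
            random_net = generate_rdpn(net, swap_factor=swap_factor, rng_seed=s)
            rows.append(propagate_on_network(random_net, p0, scheme, cfg))
    return np.vstack(rows)


@dataclass(frozen=True)
class PropagationResult:
    """Propagated weight and empirical p-value per node."""

    nodes: tuple[str, ...]
    weights: np.ndarray
    pvalues: np.ndarray
    n_networks: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": self.nodes,
                "propagated_weight": self.weights,
                "p_value": self.pvalues,
            }
        )

    def significant(self, threshold: float = 0.01) -> set[str]:
        """Nodes with p strictly below *threshold*."""
        mask = self.pvalues < threshold
        return {v for v, keep in zip(self.nodes, mask) if keep}

    def weight_of(self, node: str) -> float:
        return float(self.weights[self.nodes.index(node)])


def empirical_pvalues(
    nodes: tuple[str, ...] | list[str],
    observed: np.ndarray,
    ensemble: np.ndarray,
) -> PropagationResult:
    """Per-node permutation p-values against the RDPN null ensemble.

    ``p_v = (#{random weights >= observed} + 1) / (n + 1)``; ties count
    against the observed value, and the smallest achievable p is 1/(n+1).
    """
    ensemble = np.asarray(ensemble, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if ensemble.ndim != 2 or ensemble.shape[0] == 0:
        raise ValueError("ensemble must be a nonempty (n_networks, n_nodes) array")
    if ensemble.shape[1] != observed.shape[0]:
        raise ValueError("ensemble and observed node dimensions differ")
    n = ensemble.shape[0]
    exceed = (ensemble >= observed[None, :]).sum(axis=0)
    pvals = (exceed + 1) / (n + 1)
    return PropagationResult(
        nodes=tuple(nodes), weights=observed, pvalues=pvals, n_networks=n
    )


# ---------------------------------------------------------------------------
# RDPN disk cache: the ensemble depends only on (network, seed, swap_factor),
# so it is generated once per input network and reused across runs.


def network_hash(net: nx.Graph) -> str:
    """SHA-256 over the sorted edge list (node labels included)."""
    payload = "\n".join(
        f"{min(u, v)}\t{max(u, v)}" for u, v in sorted(
            (tuple(sorted(e)) for e in net.edges())
        )
    )
    return hashlib.sha256(payload.encode()).hexdigest()


def load_or_generate_ensemble(
    net: nx.Graph,
    cache_dir: str | Path,
    n_networks: int = 100,
    swap_factor: int = 100,
    master_seed: int = 0,
    workers: int = 1,
    force: bool = False,
) -> list[nx.Graph]:
    """Random networks from the cache, generating and caching any missing.

    The cache key is (network hash, master seed, swap factor); a manifest
    mismatch raises unless *force* truncates and regenerates.
    """
    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = cache_dir / "manifest.json"
    key = {
        "network_hash": network_hash(net),
        "master_seed": master_seed,
        "swap_factor": swap_factor,
    }
    manifest: dict = {**key, "n_networks": 0, "seeds": []}
    if manifest_path.exists():
        existing = json.loads(manifest_path.read_text())
        if {k: existing.get(k) for k in key} != key:
            if not force:
                raise ValueError(
                    f"cache at {cache_dir} was built with a different "
                    "network/seed/swap_factor; use force=True to overwrite"
                )
            for old in cache_dir.glob("rdpn_*.tsv"):
                old.unlink()
        else:
            manifest = existing
    nodes = sorted(net.nodes())
    nets: list[nx.Graph] = []
    for i in range(min(manifest["n_networks"], n_networks)):
        g: nx.Graph = nx.Graph()
        g.add_nodes_from(nodes)
        with (cache_dir / f"rdpn_{i:04d}.tsv").open() as handle:
            g.add_edges_from(
                tuple(line.rstrip("\n").split("\t")) for line in handle if line.strip()
            )
        nets.append(g)
    n_cached = len(nets)
    if n_cached:
        logger.info("RDPN cache hit: %d/%d networks", n_cached, n_networks)
    for i in range(n_cached, n_networks):
        seed = ensemble_seed(master_seed, i)
        rn = generate_rdpn(net, swap_factor=swap_factor, rng_seed=seed)
        with (cache_dir / f"rdpn_{i:04d}.tsv").open("w") as handle:
            for u, v in sorted(tuple(sorted(e)) for e in rn.edges()):
                handle.write(f"{u}\t{v}\n")
        manifest["seeds"] = manifest.get("seeds", [])[:i] + [seed]
        manifest["n_networks"] = i + 1
        manifest_path.write_text(json.dumps(manifest, indent=1))
        nets.append(rn)
    return nets
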