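"""Semi-supervised identification of phenotype-associated network modules.

Modules are grown around prior-knowledge seed genes in three steps:

(i)   extract the seed-induced sub-network (seed genes plus the edges
      among them);
(ii)  extend it with every candidate node that simultaneously has a
      significant propagated weight (p < threshold, default 0.01), is a
      direct neighbor of at least one seed, and has propagated weight
      strictly above ``w_min`` — the 75th percentile of the propagated
      weights of significant non-seed nodes; each admitted candidate brings
      its edges to seed nodes (candidate-candidate edges optionally);
(iii) report the connected components of the extended sub-network as
      modules.

Seed consolidation is quantified by an entropy criterion: with k_Mi seeds
in module M_i out of n seeds total (uncovered seeds count as singleton
modules), E = -sum p_Mi log p_Mi with p_Mi = k_Mi / n, and the
connectedness is E_max - E with E_max = log n.  Natural logarithms are
used throughout.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .significance import PropagationResult

logger = logging.getLogger("corewalk")

__all__ = [
    "SeedSet",
    "ModuleConfig",
    "Module",
    "ModuleSet",
    "ConnectednessReport",
    "top_weight_seeds",
    "seed_subnetwork",
    "compute_wmin",
    "extend_subnetwork",
    "connectedness",
]


@dataclass(frozen=True)
class SeedSet:
    """Seed genes anchoring the modules, with their provenance."""

    genes: frozenset[str]
    provenance: str = "user list"

    def in_network(self, net: nx.Graph) -> frozenset[str]:
        present = frozenset(g for g in self.genes if g in net)
        missing = len(self.genes) - len(present)
        if missing:
            logger.info("%d seed genes absent from the network; excluded", missing)
        return present


@dataclass(frozen=True)
class ModuleConfig:
    p_threshold: float = 0.01
    weight_percentile: float = 75.0
    min_module_size: int = 2
    include_candidate_edges: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.weight_percentile < 100.0):
            raise ValueError("weight percentile must be in (0, 100)")


@dataclass(frozen=True)
class Module:
    """One connected component of the (extended) seed sub-network."""

    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]
    seeds: frozenset[str]

    @property
    def size(self) -> int:
        return len(self.nodes)

    @property
    def candidates(self) -> frozenset[str]:
        return self.nodes - self.seeds


@dataclass(frozen=True)
class ModuleSet:
    """Connected components of a seed sub-network, largest first."""

    modules: tuple[Module, ...]
    graph: nx.Graph = field(repr=False, hash=False, compare=False, default=None)

    def __len__(self) -> int:
        return len(self.modules)

    def largest(self) -> Module:
        return self.modules[0]

    def filtered(self, min_size: int) -> tuple[Module, ...]:
        return tuple(m for m in self.modules if m.size >= min_size)

    def node_table(
        self, result: PropagationResult | None = None
    ) -> pd.DataFrame:
        rows = []
        lookup: Mapping[str, int] = (
            {v: i for i, v in enumerate(result.nodes)} if result else {}
        )
        for mid, module in enumerate(self.modules, start=1):
            for gene in sorted(module.nodes):
                row = {
                    "gene": gene,
                    "module_id": mid,
                    "is_seed": gene in module.seeds,
                }
                if result is not None and gene in lookup:
                    row["weight"] = float(result.weights[lookup[gene]])
                    row["p_value"] = float(result.pvalues[lookup[gene]])
                rows.append(row)
        return pd.DataFrame(rows)

    def write_edge_lists(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for mid, module in enumerate(self.modules, start=1):
            with (out_dir / f"module_{mid:03d}.tsv").open("w") as handle:
                handle.write("node1\tnode2\n")
                for u, v in sorted(module.edges):
                    handle.write(f"{u}\t{v}\n")


def _components_to_moduleset(graph: nx.Graph, seeds: frozenset[str]) -> ModuleSet:
    comps = []
    for comp in nx.connected_components(graph):
        sub = graph.subgraph(comp)
        comps.append(
            Module(
                nodes=frozenset(comp),
                edges=frozenset(tuple(sorted(e)) for e in sub.edges()),
                seeds=frozenset(comp) & seeds,
            )
        )
    comps.sort(key=lambda m: (-m.size, min(m.nodes)))
    return ModuleSet(modules=tuple(comps), graph=graph)


def top_weight_seeds(weights: Mapping[str, float], k: int = 100) -> SeedSet:
    """Fallback seed list when none is supplied: the k highest input
    weights, ties at the boundary broken lexicographically by gene."""
    ranked = sorted(weights.items(), key=lambda item: (-item[1], item[0]))
    chosen = frozenset(g for g, _ in ranked[:k])
    return SeedSet(genes=chosen, provenance=f"top-{k} fallback")


def seed_subnetwork(net: nx.Graph, seeds: SeedSet) -> ModuleSet:
    """Step (i): induced subgraph on the seed genes and their edges."""
    present = seeds.in_network(net)
    if not present:
        raise ValueError("no seed gene is present in the network")
    sub = nx.Graph(net.subgraph(present))
    return _components_to_moduleset(sub, present)


def compute_wmin(
    result: PropagationResult, seeds: SeedSet, cfg: ModuleConfig | None = None
) -> float:
    """Minimum candidate weight: the configured percentile (default 75th,
    linear interpolation) of the propagated weights of significant
    (p < threshold) nodes outside the seed set.

    Returns +inf with a warning when no significant non-seed node exists:
    the extension then adds nothing.
    """
    cfg = cfg or ModuleConfig()
    pool = [
        w
        for v, w, p in zip(result.nodes, result.weights, result.pvalues)
        if p < cfg.p_threshold and v not in seeds.genes
    ]
    if not pool:
        logger.warning("no significant non-seed nodes; w_min set to +inf")
        return math.inf
    return float(np.percentile(pool, cfg.weight_percentile))


def extend_subnetwork(
    net: nx.Graph,
    seeds: SeedSet,
    result: PropagationResult,
    cfg: ModuleConfig | None = None,
    w_min: float | None = None,
) -> ModuleSet:
    """Steps (ii)-(iii): admit candidates and split into components.

    A non-seed node enters the extended sub-network iff p < threshold,
    propagated weight > w_min (both strict), and it neighbors at least one
    seed in the full network.  Admitted candidates contribute their edges
    to seed nodes; edges between two candidates are included only when
    ``cfg.include_candidate_edges`` is set.
    """
    cfg = cfg or ModuleConfig()
    present = seeds.in_network(net)
    if not present:
        raise ValueError("no seed gene is present in the network")
    if w_min is None:
        w_min = compute_wmin(result, seeds, cfg)
    extended = nx.Graph(net.subgraph(present))
    extended.add_nodes_from(present)
    admitted: list[str] = []
    for v, w, p in zip(result.nodes, result.weights, result.pvalues):
        if v in present or v not in net:
            continue
        if p < cfg.p_threshold and w > w_min:
            seed_nbrs = [u for u in net.neighbors(v) if u in present]
            if seed_nbrs:
                admitted.append(v)
                extended.add_node(v)
                extended.add_edges_from((v, u) for u in seed_nbrs)
    if cfg.include_candidate_edges:
        admitted_set = set(admitted)
        for v in admitted:
            for u in net.neighbors(v):
                if u in admitted_set:
                    extended.add_edge(v, u)
    logger.info(
        "extension: %d candidates admitted (w_min=%.4g), %d nodes / %d edges",
        len(admitted),
        w_min,
        extended.number_of_nodes(),
        extended.number_of_edges(),
    )
    return _components_to_moduleset(extended, present)


@dataclass(frozen=True)
class ConnectednessReport:
    """Entropy-based seed-consolidation summary (natural log)."""

    entropy: float
    max_entropy: float
    connectedness: float
    module_seed_counts: tuple[int, ...]
    n_seeds: int

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "entropy": self.entropy,
                "max_entropy": self.max_entropy,
                "connectedness": self.connectedness,
                "module_seed_counts": list(self.module_seed_counts),
                "n_seeds": self.n_seeds,
            },
            indent=1,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


def connectedness(
    modules: ModuleSet | Iterable[Module], seeds: SeedSet, net: nx.Graph | None = None
) -> ConnectednessReport:
    """Seed-distribution entropy E versus the maximum E_max = log n.

    Seeds not covered by any module count as singleton modules.  The
    connectedness E_max - E is 0 when every seed is isolated and log n when
    all n seeds share one module.  *net* restricts the seed universe to
    network members; otherwise all seeds count.
    """
    mods = modules.modules if isinstance(modules, ModuleSet) else tuple(modules)
    universe = seeds.in_network(net) if net is not None else seeds.genes
    n = len(universe)
    if n < 2:
        raise ValueError("connectedness needs at least 2 seeds in the network")
    counts = [len(m.seeds & universe) for m in mods if m.seeds & universe]
    covered = sum(counts)
    counts.extend([1] * (n - covered))  # uncovered seeds: singleton modules
    probs = np.array(counts, dtype=float) / n
    entropy = float(-(probs * np.log(probs)).sum())
    e_max = math.log(n)
    return ConnectednessReport(
        entropy=entropy,
        max_entropy=e_max,
        connectedness=e_max - entropy,
        module_seed_counts=tuple(counts),
        n_seeds=n,
    )
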