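"""Interaction-network input, filtering and node characterization.

A protein-protein interaction (PPI) network is modelled as an undirected
simple graph over gene identifiers.  Propagation requires a connected
scaffold, so callers reduce to the largest connected component before
building a transition matrix.  Each node carries two centralities:

* **degree** ``d`` — the number of interaction partners (local).
* **core** ``k`` — the k-shell index from k-core decomposition: the largest
  ``k`` such that the node survives in the maximal subgraph of minimum
  degree ``k`` (global).  Hubs of star-like substructures, typical of
  bait/prey experimental bias, have high degree but low core, which is what
  the core-based transition normalizations exploit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import networkx as nx
import pandas as pd

logger = logging.getLogger("corewalk")

__all__ = [
    "EdgeListFormatError",
    "EmptyNetworkError",
    "NodeMetrics",
    "read_edge_list",
    "largest_connected_component",
    "k_shell_decomposition",
    "network_summary",
    "write_gml",
]


class EdgeListFormatError(ValueError):
    """A malformed line in a tab-separated edge-list file."""


class EmptyNetworkError(ValueError):
    """No edges survive reading/filtering."""


@dataclass(frozen=True)
class NodeMetrics:
    """Per-node degree and core (k-shell index) of a connected graph."""

    degree: Mapping[str, int]
    core: Mapping[str, int]

    def as_frame(self) -> pd.DataFrame:
        nodes = sorted(self.degree)
        return pd.DataFrame(
            {
                "gene": nodes,
                "degree": [self.degree[v] for v in nodes],
                "core": [self.core[v] for v in nodes],
            }
        )


def read_edge_list(
    path: str | Path, confidence_threshold: float | None = None
) -> nx.Graph:
    """Read a 2- or 3-column TSV edge list into a simple undirected graph.

    Columns are ``node1 TAB node2 [TAB confidence]``; lines starting with
    ``#`` are treated as comments/headers.  When *confidence_threshold* is
    given, only edges with confidence strictly above the threshold are kept
    (mirroring high-confidence PPI extraction, e.g. score > 0.95).
    Self-loops and duplicate edges are dropped with a logged count.

    Raises
    ------
    EdgeListFormatError
        on a line with fewer than two columns, or a non-numeric confidence,
        or a threshold given for a 2-column file.
    EmptyNetworkError
        if no edges remain after filtering.
    """
    path = Path(path)
    graph: nx.Graph = nx.Graph()
    n_dropped_conf = 0
    n_self = 0
    n_dup = 0
    n_edges_read = 0
    with path.open() as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise EdgeListFormatError(
                    f"{path}:{lineno}: expected at least two tab-separated "
                    f"node columns, got {line!r}"
                )
            u, v = fields[0].strip(), fields[1].strip()
            confidence: float | None = None
            if len(fields) >= 3 and fields[2].strip():
                try:
                    confidence = float(fields[2])
                except ValueError as exc:
                    raise EdgeListFormatError(
                        f"{path}:{lineno}: non-numeric confidence {fields[2]!r}"
                    ) from exc
            n_edges_read += 1
            if confidence_threshold is not None:
                if confidence is None:
                    raise EdgeListFormatError(
                        f"{path}:{lineno}: confidence threshold given but "
                        "line has no confidence column"
                    )
                if not confidence > confidence_threshold:
                    n_dropped_conf += 1
                    continue
            if u == v:
                n_self += 1
                logger.warning("%s:%d: dropping self-loop %s-%s", path, lineno, u, v)
                continue
            if graph.has_edge(u, v):
                n_dup += 1
                continue
            graph.add_edge(u, v, **({} if confidence is None else {"confidence": confidence}))
    if graph.number_of_edges() == 0:
        raise EmptyNetworkError(
            f"{path}: empty network after filtering "
            f"({n_edges_read} edges read, {n_dropped_conf} below threshold)"
        )
    logger.info(
        "read %s: %d nodes, %d edges kept (%d read; dropped %d low-confidence, "
        "%d self-loops, %d duplicates)",
        path,
        graph.number_of_nodes(),
        graph.number_of_edges(),
        n_edges_read,
        n_dropped_conf,
        n_self,
        n_dup,
    )
    return graph


def largest_connected_component(net: nx.Graph) -> nx.Graph:
    """Induced subgraph on the largest connected component.

    Ties in component size are broken deterministically by the
    lexicographically smallest member node.
    """
    if net.number_of_nodes() == 0:
        raise EmptyNetworkError("cannot take the component of an empty network")
    components = [set(c) for c in nx.connected_components(net)]
    # size first; among equal sizes prefer the lexicographically smallest member
    best = sorted(components, key=lambda c: (-len(c), min(c)))[0]
    excluded = net.number_of_nodes() - len(best)
    if excluded:
        logger.info(
            "largest connected component: kept %d nodes, excluded %d",
            len(best),
            excluded,
        )
    return net.subgraph(best).copy()


def k_shell_decomposition(net: nx.Graph) -> NodeMetrics:
    """Degree and core of every node via k-shell (k-core) decomposition.

    Peels nodes of degree <= k in rounds for k = 1, 2, ...; a node's core is
    the shell index at which it is removed, equivalently the largest k such
    that it belongs to the k-core.  Degrees refer to the input graph.

    Raises ``ValueError`` on a disconnected graph: reduce with
    :func:`largest_connected_component` first.
    """
    if net.number_of_nodes() < 2:
        raise ValueError("k-shell decomposition needs at least 2 nodes")
    if not nx.is_connected(net):
        raise ValueError(
            "graph is disconnected; apply largest_connected_component() first"
        )
    core = nx.core_number(net)
    degree = dict(net.degree())
    return NodeMetrics(degree=degree, core=core)


def network_summary(net: nx.Graph, metrics: NodeMetrics | None = None) -> pd.DataFrame:
    """Per-node summary table (gene, degree[, core]) sorted by gene."""
    nodes = sorted(net.nodes())
    data = {"gene": nodes, "degree": [net.degree(v) for v in nodes]}
    if metrics is not None:
        data["core"] = [metrics.core[v] for v in nodes]
    return pd.DataFrame(data)


def write_gml(net: nx.Graph, path: str | Path) -> None:
    nx.write_gml(net, str(path))
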