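"""Adjacency normalization and random walk with restart (RWR).

The walk follows ``p_k = alpha * p0 + (1 - alpha) * W p_{k-1}`` with
restart probability ``alpha`` (default 0.8) and a column-stochastic
transition matrix ``W``; columns are "from" nodes, so ``W[:, j]`` is the
distribution over the neighbors a walker at ``j`` steps to.  On a connected
graph the process converges to the steady state

    p = alpha * (I - (1 - alpha) W)^{-1} p0,

computed here by a sparse direct solve.

Four normalizations of the adjacency matrix A are supported:

``degree``
    classic ``W = A D^{-1}``: each neighbor of j receives 1/d_j.
``core``
    neighbor i of j receives ``k_i / sum(k_l for l in N(j))`` — walkers are
    steered toward deeply embedded (high-core) nodes.
``diff``
    raw weight ``1 / ((d_i - k_i) + 1)`` per neighbor, column-rescaled —
    penalizes nodes whose degree far exceeds their core (study-bias hubs).
``ratio``
    raw weight ``k_i / d_i`` per neighbor, column-rescaled; the ratio is
    always <= 1 since the core never exceeds the degree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .graph_core import NodeMetrics

logger = logging.getLogger("corewalk")

__all__ = [
    "SCHEMES",
    "PropagationConfig",
    "TransitionMatrix",
    "normalize_adjacency",
    "rwr_closed_form",
    "rwr_iterative",
    "read_weight_table",
    "read_seed_list",
    "weights_to_vector",
    "ranking_table",
]

SCHEMES = ("degree", "core", "diff", "ratio")


@dataclass(frozen=True)
class PropagationConfig:
    """RWR parameters.

    alpha : restart probability in (0, 1], default 0.8.
    tol : iterative-solver convergence tolerance on max absolute change.
    max_iter : iteration cap for the iterative solver.
    solver : "closed_form" (sparse direct solve) or "iterative".
    """

    alpha: float = 0.8
    tol: float = 1e-8
    max_iter: int = 10_000
    solver: str = "closed_form"

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.tol <= 0:
            raise ValueError("tolerance must be positive")


@dataclass(frozen=True)
class TransitionMatrix:
    """Column-stochastic transition matrix over a fixed node ordering.

    The ordering is the sorted node identifiers, shared by all weight
    vectors and outputs so that runs are reproducible bit-for-bit.
    """

    matrix: sp.csc_matrix
    nodes: tuple[str, ...]
    scheme: str
    index: Mapping[str, int] = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        if not self.index:
            object.__setattr__(
                self, "index", {v: i for i, v in enumerate(self.nodes)}
            )


def normalize_adjacency(
    net: nx.Graph, metrics: NodeMetrics, scheme: str
) -> TransitionMatrix:
    """Build the column-stochastic transition matrix under *scheme*.

    Requires a connected graph and metrics covering every node.  Raw per-
    neighbor weights (see module docstring) are assembled column by column
    and each column divided by its own sum; for ``degree`` and ``core`` the
    raw columns already sum to d_j resp. sum-of-neighbor-cores, so the
    rescale is exactly the textbook definition.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    nodes = tuple(sorted(net.nodes()))
    index = {v: i for i, v in enumerate(nodes)}
    missing = [v for v in nodes if v not in metrics.core or v not in metrics.degree]
    if missing:
        raise ValueError(f"metrics missing for nodes: {missing[:5]}")
    n = len(nodes)
    deg = np.array([metrics.degree[v] for v in nodes], dtype=float)
    core = np.array([metrics.core[v] for v in nodes], dtype=float)

    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    for j, v in enumerate(nodes):
        nbrs = [index[u] for u in net.neighbors(v)]
        if not nbrs:
            raise ValueError(f"node {v!r} has no neighbors; graph must be connected")
        nbrs.sort()
        if scheme == "degree":
            raw = np.full(len(nbrs), 1.0)
        elif scheme == "core":
            raw = core[nbrs]
        elif scheme == "diff":
            raw = 1.0 / ((deg[nbrs] - core[nbrs]) + 1.0)
        else:  # ratio
            raw = core[nbrs] / deg[nbrs]
        total = raw.sum()
        if total <= 0:  # impossible on simple connected graphs (cores >= 1)
            raise ValueError(f"zero column sum for node {v!r}")
        rows.extend(nbrs)
        cols.extend([j] * len(nbrs))
        vals.extend(raw / total)
    matrix = sp.csc_matrix((vals, (rows, cols)), shape=(n, n))
    return TransitionMatrix(matrix=matrix, nodes=nodes, scheme=scheme)


def rwr_closed_form(
    W: TransitionMatrix, p0: np.ndarray, cfg: PropagationConfig | None = None
) -> np.ndarray:
    """Steady-state weights by solving (I - (1-alpha) W) p = alpha p0."""
    cfg = cfg or PropagationConfig()
    p0 = np.asarray(p0, dtype=float)
    if p0.shape != (len(W.nodes),):
        raise ValueError("p0 length does not match the node ordering")
    if cfg.alpha == 1.0:
        return p0.copy()
    n = len(W.nodes)
    system = sp.identity(n, format="csc") - (1.0 - cfg.alpha) * W.matrix
    p = spla.spsolve(system.tocsc(), cfg.alpha * p0)
    return np.asarray(p, dtype=float)


def rwr_iterative(
    W: TransitionMatrix, p0: np.ndarray, cfg: PropagationConfig | None = None
) -> tuple[np.ndarray, int]:
    """Power iteration of the restart recurrence until max |change| < tol.

    Returns ``(p, n_iterations)``; raises ``RuntimeError`` with the final
    residual if *max_iter* is reached without convergence.
    """
    cfg = cfg or PropagationConfig()
    p0 = np.asarray(p0, dtype=float)
    if p0.shape != (len(W.nodes),):
        raise ValueError("p0 length does not match the node ordering")
    p = p0.copy()
    alpha = cfg.alpha
    for it in range(1, cfg.max_iter + 1):
        p_next = alpha * p0 + (1.0 - alpha) * (W.matrix @ p)
        residual = float(np.max(np.abs(p_next - p)))
        p = p_next
        if residual < cfg.tol:
            return p, it
    raise RuntimeError(
        f"RWR did not converge in {cfg.max_iter} iterations "
        f"(final residual {residual:.3e})"
    )


def read_weight_table(path: str | Path) -> dict[str, float]:
    """2-column TSV ``gene TAB weight``; '#'-prefixed lines are comments."""
    weights: dict[str, float] = {}
    with Path(path).open() as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'gene<TAB>weight'")
            weights[fields[0].strip()] = float(fields[1])
    return weights


def read_seed_list(path: str | Path) -> list[str]:
    """One gene per line; '#'-prefixed lines are comments."""
    seeds: list[str] = []
    with Path(path).open() as handle:
        for raw in handle:
            line = raw.strip()
            if line and not line.startswith("#"):
                seeds.append(line)
    return seeds


def weights_to_vector(
    nodes: Sequence[str], weights: Mapping[str, float]
) -> np.ndarray:
    """Align a gene->weight mapping to the node ordering.

    Genes absent from the network are dropped with a logged count; network
    nodes without a weight carry 0.  Negative or non-finite weights are
    rejected.
    """
    index = {v: i for i, v in enumerate(nodes)}
    p0 = np.zeros(len(nodes), dtype=float)
    dropped = 0
    for gene, w in weights.items():
        if not np.isfinite(w) or w < 0:
            raise ValueError(f"weight for {gene!r} must be finite and >= 0, got {w}")
        i = index.get(gene)
        if i is None:
            dropped += 1
            continue
        p0[i] = w
    if dropped:
        logger.info("%d weighted genes not covered by the network; dropped", dropped)
    return p0


def ranking_table(
    W: TransitionMatrix,
    metrics: NodeMetrics,
    p0: np.ndarray,
    propagated: np.ndarray,
) -> pd.DataFrame:
    """Per-node output table: gene, input_weight, degree, core,
    propagated_weight, rank (1 = highest propagated weight; ties broken by
    gene identifier via the stable sort on the sorted node ordering)."""
    frame = pd.DataFrame(
        {
            "gene": W.nodes,
            "input_weight": p0,
            "degree": [metrics.degree[v] for v in W.nodes],
            "core": [metrics.core[v] for v in W.nodes],
            "propagated_weight": propagated,
        }
    )
    order = np.argsort(-frame["propagated_weight"].to_numpy(), kind="stable")
    ranks = np.empty(len(order), dtype=int)
    ranks[order] = np.arange(1, len(order) + 1)
    frame["rank"] = ranks
    return frame.sort_values("rank", ignore_index=True)
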