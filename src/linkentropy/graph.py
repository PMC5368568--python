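"""Undirected simple-graph container, file I/O, descriptive statistics,
fixtures and seeded synthetic generators.

Node labels are strings internally. Matrix row order (and hence every
factorization result) follows a deterministic sorted label order in which
numeric labels sort numerically, so repeated runs index nodes identically.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Graph",
    "GraphFormatError",
    "AdjacencyMatrix",
    "NetworkStats",
    "canonical_edge",
    "read_graph",
    "write_edgelist",
    "build_adjacency",
    "network_stats",
    "fixture_three_triangles",
    "fixture_karate",
    "generate_planted_partition",
    "generate_barbell",
]


class GraphFormatError(ValueError):
    """Raised when an input file cannot be interpreted as a simple graph."""


def _label_key(label: str):
    """Sort key placing numeric labels in numeric order before other labels."""
    try:
        return (0, float(label), label)
    except ValueError:
        return (1, math.inf, label)


def canonical_edge(u: str, v: str) -> tuple[str, str]:
    """Return the unordered edge {u, v} as a canonically ordered tuple."""
    u, v = str(u), str(v)
    return (u, v) if _label_key(u) <= _label_key(v) else (v, u)


class Graph:
    """Undirected, unweighted simple graph with deterministic node order.

    Construction drops self-loops and collapses duplicate edges silently;
    :func:`read_graph` is the entry point that counts and logs them.
    ``metadata`` carries generator ground truth (e.g. planted inter-block
    edges) and is never consulted by any scoring code.
    """

    def __init__(
        self,
        edges: Iterable[tuple] = (),
        nodes: Iterable = (),
        metadata: Mapping | None = None,
    ):
        g = nx.Graph()
        for u in nodes:
            g.add_node(str(u))
        for u, v in edges:
            u, v = str(u), str(v)
            g.add_node(u)
            g.add_node(v)
            if u != v:
                g.add_edge(u, v)
        self._nx = g
        self.metadata: dict = dict(metadata or {})

    # -- basic accessors -------------------------------------------------

    @property
    def nodes(self) -> list[str]:
        return sorted(self._nx.nodes, key=_label_key)

    @property
    def edges(self) -> list[tuple[str, str]]:
        es = [canonical_edge(u, v) for u, v in self._nx.edges]
        return sorted(es, key=lambda e: (_label_key(e[0]), _label_key(e[1])))

    @property
    def n_nodes(self) -> int:
        return self._nx.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._nx.number_of_edges()

    def degree(self, u) -> int:
        return self._nx.degree[str(u)]

    def neighbors(self, u) -> list[str]:
        return sorted(self._nx.neighbors(str(u)), key=_label_key)

    def has_edge(self, u, v) -> bool:
        return self._nx.has_edge(str(u), str(v))

    def to_networkx(self) -> nx.Graph:
        """A copy of the underlying networkx graph (safe to mutate)."""
        return self._nx.copy()

    def is_connected(self) -> bool:
        return self.n_nodes > 0 and nx.is_connected(self._nx)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Graph(n_nodes={self.n_nodes}, n_edges={self.n_edges})"

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Graph)
            and set(self._nx.nodes) == set(other._nx.nodes)
            and self.edges == other.edges
        )


# -- file I/O ------------------------------------------------------------


def read_graph(
    path,
    format: str = "edgelist",
    symmetrize: bool = False,
    ignore_weights: bool = False,
) -> Graph:
    """Read an undirected, unweighted graph from ``path``.

    ``edgelist``: two whitespace-separated node labels per line; text after
    ``#`` is a comment. Duplicate edges are collapsed and self-loops
    dropped, with counts logged. ``gml``: parsed with networkx; directed
    input is rejected unless ``symmetrize`` is set, and edge weights are
    rejected unless ``ignore_weights`` is set (they are then discarded).
    """
    if format == "edgelist":
        g = _read_edgelist(path)
    elif format == "gml":
        g = _read_gml(path, symmetrize=symmetrize, ignore_weights=ignore_weights)
    else:
        raise GraphFormatError(f"unknown graph format {format!r} (use 'edgelist' or 'gml')")
    if g.n_nodes == 0:
        raise GraphFormatError(f"{path}: empty graph (no nodes parsed)")
    return g


def _read_edgelist(path) -> Graph:
    g = Graph()
    n_loops = n_dups = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2:
                raise GraphFormatError(
                    f"{path}: line {lineno}: expected two node labels, got {len(parts)}"
                )
            u, v = parts
            if u == v:
                n_loops += 1
                g._nx.add_node(u)
                continue
            if g._nx.has_edge(u, v):
                n_dups += 1
                continue
            g._nx.add_edge(u, v)
    if n_loops:
        logger.warning("%s: dropped %d self-loop(s)", path, n_loops)
    if n_dups:
        logger.warning("%s: collapsed %d duplicate edge(s)", path, n_dups)
    return g


def _read_gml(path, symmetrize: bool, ignore_weights: bool) -> Graph:
    raw = nx.read_gml(path, label="label")
    if raw.is_directed():
        if not symmetrize:
            raise GraphFormatError(
                f"{path}: directed graph; pass symmetrize=True to treat "
                "each arc as an undirected edge"
            )
        raw = raw.to_undirected()
    weighted = any("weight" in d for _, _, d in raw.edges(data=True))
    if weighted and not ignore_weights:
        raise GraphFormatError(
            f"{path}: weighted graph; pass ignore_weights=True to discard weights"
        )
    if raw.is_multigraph():
        raw = nx.Graph(raw)
    return Graph(raw.edges, nodes=raw.nodes)


def write_edgelist(g: Graph, path) -> None:
    """Write one canonical ``u v`` pair per line, UTF-8."""
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in g.edges:
            fh.write(f"{u} {v}\n")


# -- adjacency and statistics -------------------------------------------


@dataclass(frozen=True)
class AdjacencyMatrix:
    """Symmetric 0/1 matrix with a unit diagonal (each node linked to itself),
    the convention under which the membership factorization operates."""

    values: np.ndarray
    labels: tuple[str, ...]

    @property
    def node_index(self) -> dict[str, int]:
        return {lab: i for i, lab in enumerate(self.labels)}

    @property
    def n(self) -> int:
        return len(self.labels)


def build_adjacency(g: Graph) -> AdjacencyMatrix:
    """Adjacency matrix of ``g`` with ones on the diagonal."""
    if g.n_nodes == 0:
        raise ValueError("cannot build adjacency matrix of an empty graph")
    labels = tuple(g.nodes)
    index = {lab: i for i, lab in enumerate(labels)}
    a = np.eye(len(labels))
    for u, v in g.edges:
        i, j = index[u], index[v]
        a[i, j] = a[j, i] = 1.0
    return AdjacencyMatrix(values=a, labels=labels)


@dataclass(frozen=True)
class NetworkStats:
    """Descriptive statistics: size, degrees, degree heterogeneity
    ⟨k²⟩/⟨k⟩², degree assortativity and mean local clustering."""

    n_nodes: int
    n_edges: int
    mean_degree: float
    max_degree: int
    heterogeneity: float
    assortativity: float
    clustering: float

    def as_dict(self) -> dict:
        return {
            "N": self.n_nodes,
            "E": self.n_edges,
            "mean_k": self.mean_degree,
            "k_max": self.max_degree,
            "H_k": self.heterogeneity,
            "r": self.assortativity,
            "C": self.clustering,
        }


def network_stats(g: Graph) -> NetworkStats:
    """Compute the descriptor tuple (N, E, ⟨k⟩, k_max, H_k, r, C).

    Clustering is the mean local clustering coefficient (nodes of degree
    < 2 contribute 0). Assortativity is the Pearson correlation of endpoint
    degrees over edges; on regular graphs it is undefined and returned as
    NaN with a warning.
    """
    if g.n_nodes < 2 or g.n_edges < 1:
        raise ValueError("network_stats requires at least 2 nodes and 1 edge")
    deg = np.array([g.degree(u) for u in g.nodes], dtype=float)
    mean_k = float(deg.mean())
    h_k = float((deg**2).mean() / mean_k**2)
    if deg.max() == deg.min():
        logger.warning("all degrees equal: assortativity undefined, returning NaN")
        r = math.nan
    else:
        r = float(nx.degree_assortativity_coefficient(g._nx))
    c = float(nx.average_clustering(g._nx))
    return NetworkStats(
        n_nodes=g.n_nodes,
        n_edges=g.n_edges,
        mean_degree=mean_k,
        max_degree=int(deg.max()),
        heterogeneity=h_k,
        assortativity=r,
        clustering=c,
    )


# -- fixtures and synthetic generators ----------------------------------

#: three triangles {1,2,3}, {4,5,6}, {7,8,9} joined by bridges 1-4, 5-7, 5-8
_THREE_TRIANGLES_EDGES = [
    (1, 2), (1, 3), (2, 3),
    (4, 5), (4, 6), (5, 6),
    (7, 8), (7, 9), (8, 9),
    (1, 4), (5, 7), (5, 8),
]


def fixture_three_triangles() -> Graph:
    """The 9-node worked-example graph: three triangles bridged at 1-4,
    5-7 and 5-8. Node 5 straddles two triangles and has degree 4."""
    return Graph(_THREE_TRIANGLES_EDGES)


def fixture_karate() -> Graph:
    """Zachary's karate-club friendship network (34 nodes, 78 edges),
    relabelled 1..34."""
    base = nx.karate_club_graph()
    return Graph(((str(u + 1), str(v + 1)) for u, v in base.edges))


def generate_planted_partition(
    n_per_block: int, p_in: float, p_out: float, seed: int
) -> Graph:
    """Two-block planted-partition random graph.

    Within-block pairs are linked independently with probability ``p_in``,
    between-block pairs with ``p_out`` (``p_out < p_in``). The planted
    structure is recorded in ``metadata``: ``blocks`` (two node tuples) and
    ``inter_block_edges`` (ground-truth bridge set). Same seed, same graph.
    """
    if n_per_block < 2:
        raise ValueError("n_per_block must be >= 2")
    if not (0.0 <= p_out < p_in <= 1.0):
        raise ValueError("require 0 <= p_out < p_in <= 1")
    rng = np.random.default_rng(seed)
    n = 2 * n_per_block
    labels = [str(i + 1) for i in range(n)]
    block = [0] * n_per_block + [1] * n_per_block
    edges: list[tuple[str, str]] = []
    inter: list[tuple[str, str]] = []
    for i in range(n):
        for j in range(i + 1, n):
            p = p_in if block[i] == block[j] else p_out
            if rng.random() < p:
                e = canonical_edge(labels[i], labels[j])
                edges.append(e)
                if block[i] != block[j]:
                    inter.append(e)
    g = Graph(
        edges,
        nodes=labels,
        metadata={
            "blocks": (tuple(labels[:n_per_block]), tuple(labels[n_per_block:])),
            "inter_block_edges": frozenset(inter),
            "seed": seed,
        },
    )
    if not g.is_connected():
        logger.warning(
            "planted partition (n_per_block=%d, p_in=%g, p_out=%g, seed=%d) "
            "is disconnected", n_per_block, p_in, p_out, seed,
        )
    return g


def generate_barbell(clique_size: int) -> Graph:
    """Two complete graphs of ``clique_size`` nodes joined by one bridge.

    Nodes 1..c form the first clique, c+1..2c the second; the bridge runs
    between node c and node c+1.
    """
    if clique_size < 3:
        raise ValueError("clique_size must be >= 3")
    c = clique_size
    edges = []
    for base in (0, c):
        for i in range(c):
            for j in range(i + 1, c):
                edges.append((str(base + i + 1), str(base + j + 1)))
    edges.append((str(c), str(c + 1)))
    return Graph(edges, metadata={"bridge": canonical_edge(str(c), str(c + 1))})
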