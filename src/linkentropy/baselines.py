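"""Six benchmark edge-significance indices.

Edge betweenness centrality, degree product, bridgeness, diffusion
importance, topological overlap and the ERW-Kpath random-walk estimate of
k-path edge centrality — the standard topological comparators for ranking
edges by their role in global connectivity.
"""

from __future__ import annotations

import logging
import math
import time

import networkx as nx
import numpy as np

from .graph import Graph, canonical_edge
from .le import EdgeScoreTable, score_le

logger = logging.getLogger(__name__)

__all__ = [
    "edge_betweenness",
    "degree_product",
    "bridgeness",
    "diffusion_importance",
    "topological_overlap",
    "erw_kpath",
    "score_method",
    "CliqueTimeoutError",
    "METHODS",
]


class CliqueTimeoutError(RuntimeError):
    """Maximum-clique enumeration exceeded its time budget."""


def edge_betweenness(g: Graph) -> EdgeScoreTable:
    """Edge betweenness centrality.

    For each edge E, the sum over unordered node pairs {s, t} of
    σ_st(E)/σ_st — the fraction of shortest s–t paths through E. Pairs in
    different components contribute nothing.
    """
    if g.n_nodes == 0:
        raise ValueError("graph is empty")
    raw = nx.edge_betweenness_centrality(g.to_networkx(), normalized=False)
    scores = {canonical_edge(u, v): float(s) for (u, v), s in raw.items()}
    return EdgeScoreTable(method="betweenness", scores=scores)


def degree_product(g: Graph, theta: float = 1.0) -> EdgeScoreTable:
    """(k_x · k_y)^θ for each edge; θ = 1 by default since only the edge
    order matters downstream."""
    scores = {
        (u, v): float((g.degree(u) * g.degree(v)) ** theta) for u, v in g.edges
    }
    return EdgeScoreTable(method="degree_product", scores=scores,
                          params={"theta": theta})


def _max_clique_sizes(g: Graph, timeout: float):
    """Largest-clique size containing each node and each edge, by exact
    enumeration of maximal cliques."""
    node_size: dict[str, int] = {u: 1 for u in g.nodes}
    edge_size: dict[tuple[str, str], int] = {e: 2 for e in g.edges}
    deadline = time.monotonic() + timeout
    for clique in nx.find_cliques(g.to_networkx()):
        if time.monotonic() > deadline:
            raise CliqueTimeoutError(
                f"maximum-clique enumeration exceeded {timeout:g} s; "
                "skip the bridgeness index for this network"
            )
        s = len(clique)
        for i, u in enumerate(clique):
            if s > node_size[u]:
                node_size[u] = s
            for v in clique[i + 1:]:
                e = canonical_edge(u, v)
                if e in edge_size and s > edge_size[e]:
                    edge_size[e] = s
    return node_size, edge_size


def bridgeness(g: Graph, timeout: float = 60.0) -> EdgeScoreTable:
    """Bridgeness: sqrt(S_x · S_y) / S_e, where S_x, S_y, S_e are the sizes
    of the largest cliques containing endpoint x, endpoint y and the edge
    itself. Large for edges joining two cliques; exactly 1 inside a clique
    that is maximal for both endpoints.

    Uses exact maximal-clique enumeration and raises
    :class:`CliqueTimeoutError` if it exceeds ``timeout`` seconds — on
    dense networks the enumeration is genuinely exponential and the index
    is customarily skipped rather than approximated.
    """
    node_size, edge_size = _max_clique_sizes(g, timeout)
    scores = {
        (u, v): math.sqrt(node_size[u] * node_size[v]) / edge_size[(u, v)]
        for u, v in g.edges
    }
    return EdgeScoreTable(method="bridgeness", scores=scores,
                          params={"timeout": timeout})


def diffusion_importance(g: Graph) -> EdgeScoreTable:
    """Diffusion importance: (n_x→y + n_y→x) / 2 per edge, where n_x→y is
    the number of y's links leading outside x's closed neighborhood —
    the channels through which a contagion crossing the edge can reach
    new territory."""
    nbrs = {u: set(g.neighbors(u)) for u in g.nodes}
    scores = {}
    for u, v in g.edges:
        n_uv = len(nbrs[v] - nbrs[u] - {u})
        n_vu = len(nbrs[u] - nbrs[v] - {v})
        scores[(u, v)] = 0.5 * (n_uv + n_vu)
    return EdgeScoreTable(method="diffusion", scores=scores)


def topological_overlap(g: Graph) -> EdgeScoreTable:
    """Topological overlap: n_ij / ((k_i − 1) + (k_j − 1) − n_ij) with n_ij
    the number of common neighbors. A zero denominator (two degree-1
    endpoints) scores 0: such an edge has no common friends."""
    nbrs = {u: set(g.neighbors(u)) for u in g.nodes}
    scores = {}
    for u, v in g.edges:
        n_common = len(nbrs[u] & nbrs[v])
        denom = (g.degree(u) - 1) + (g.degree(v) - 1) - n_common
        scores[(u, v)] = n_common / denom if denom > 0 else 0.0
    return EdgeScoreTable(method="overlap", scores=scores)


def erw_kpath(
    g: Graph, k: int = 20, rho: int | None = None, seed: int = 0
) -> EdgeScoreTable:
    """ERW-Kpath: Monte-Carlo k-path edge centrality.

    Repeats ``rho`` (default 50·|E|) self-avoiding-edge random walks: pick
    a source uniformly, take up to ``k`` steps choosing uniformly among
    incident edges not yet traversed in this walk, stopping early when none
    remain; every traversed edge's counter is incremented. The score is
    counter/rho. Long walks (k = 20) spread the counts enough to separate
    high- from low-centrality edges.
    """
    if k < 1 or (rho is not None and rho < 1):
        raise ValueError("require k >= 1 and rho >= 1")
    m = g.n_edges
    if rho is None:
        rho = 50 * m
    rng = np.random.default_rng(seed)
    nodes = g.nodes
    adj = {u: g.neighbors(u) for u in nodes}
    counts = {e: 0 for e in g.edges}
    for _ in range(rho):
        cur = nodes[rng.integers(len(nodes))]
        used: set[tuple[str, str]] = set()
        for _ in range(k):
            cands = [v for v in adj[cur] if canonical_edge(cur, v) not in used]
            if not cands:
                break
            nxt = cands[rng.integers(len(cands))]
            e = canonical_edge(cur, nxt)
            used.add(e)
            counts[e] += 1
            cur = nxt
    scores = {e: c / rho for e, c in counts.items()}
    return EdgeScoreTable(method="kpath", scores=scores,
                          params={"k": k, "rho": rho, "seed": seed})


#: dispatch table: method name -> callable(graph, **params)
METHODS = {
    "le": score_le,
    "betweenness": edge_betweenness,
    "degree_product": degree_product,
    "bridgeness": bridgeness,
    "diffusion": diffusion_importance,
    "overlap": topological_overlap,
    "kpath": erw_kpath,
}


def score_method(g: Graph, method: str, **params) -> EdgeScoreTable:
    """Uniform dispatch over the seven edge indices.

    ``params`` are forwarded to the chosen index (``k``/``n_restarts``/
    ``seed`` for le, ``theta`` for degree_product, ``k``/``rho``/``seed``
    for kpath, ``timeout`` for bridgeness) and recorded in the returned
    table.
    """
    if method not in METHODS:
        raise ValueError(
            f"unknown method {method!r}; valid methods: {', '.join(sorted(METHODS))}"
        )
    return METHODS[method](g, **params)
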