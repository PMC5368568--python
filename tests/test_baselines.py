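"""Benchmark edge indices, each checked against direct definitions and,
for the combinatorial ones, brute-force oracles on small graphs."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest

from linkentropy import (
    CliqueTimeoutError,
    Graph,
    bridgeness,
    canonical_edge,
    degree_product,
    diffusion_importance,
    edge_betweenness,
    erw_kpath,
    generate_barbell,
    score_method,
    topological_overlap,
)

# -- independent oracles -------------------------------------------------


def bf_edge_betweenness(g: Graph) -> dict:
    """Sum of shortest-path fractions per edge by explicit enumeration of
    all simple paths (feasible for <= 8 nodes)."""
    h = g.to_networkx()
    scores = {e: 0.0 for e in g.edges}
    for s, t in itertools.combinations(g.nodes, 2):
        if not nx.has_path(h, s, t):
            continue
        paths = list(nx.all_simple_paths(h, s, t))
        shortest = min(len(p) for p in paths)
        geodesics = [p for p in paths if len(p) == shortest]
        for p in geodesics:
            for u, v in zip(p, p[1:]):
                scores[canonical_edge(u, v)] += 1 / len(geodesics)
    return scores


def bf_clique_sizes(g: Graph):
    """Largest clique containing each node/edge by subset enumeration."""
    h = g.to_networkx()
    nodes = g.nodes
    node_best = {u: 1 for u in nodes}
    edge_best = {e: 2 for e in g.edges}
    for r in range(2, len(nodes) + 1):
        for sub in itertools.combinations(nodes, r):
            if all(h.has_edge(u, v) for u, v in itertools.combinations(sub, 2)):
                for u in sub:
                    node_best[u] = max(node_best[u], r)
                for u, v in itertools.combinations(sub, 2):
                    e = canonical_edge(u, v)
                    edge_best[e] = max(edge_best[e], r)
    return node_best, edge_best


def _random_connected_graph(n: int, seed: int) -> Graph:
    rng = np.random.default_rng(seed)
    while True:
        h = nx.gnp_random_graph(n, 0.45, seed=int(rng.integers(2**31)))
        if nx.is_connected(h):
            return Graph(((str(u), str(v)) for u, v in h.edges))


# -- edge betweenness ----------------------------------------------------


class TestEdgeBetweenness:
    def test_path_graph(self, path3):
        t = edge_betweenness(path3)
        assert t[("a", "b")] == pytest.approx(2.0)
        assert t[("b", "c")] == pytest.approx(2.0)

    def test_four_cycle_symmetric(self):
        g = Graph([(1, 2), (2, 3), (3, 4), (4, 1)])
        t = edge_betweenness(g)
        assert all(s == pytest.approx(2.0) for s in t.scores.values())

    def test_barbell_bridge_counts_all_cross_pairs(self, barbell3):
        t = edge_betweenness(barbell3)
        assert t[barbell3.metadata["bridge"]] == pytest.approx(9.0)

    @pytest.mark.parametrize("n,seed", [(n, s) for n in (4, 5, 6, 7, 8)
                                        for s in (0, 1, 2)])
    def test_matches_brute_force_on_small_graphs(self, n, seed):
        g = _random_connected_graph(n, seed)
        t = edge_betweenness(g)
        oracle = bf_edge_betweenness(g)
        for e in g.edges:
            assert t[e] == pytest.approx(oracle[e], abs=1e-9)


# -- degree product ------------------------------------------------------


class TestDegreeProduct:
    def test_star(self):
        g = Graph([("c", "l1"), ("c", "l2"), ("c", "l3")])
        t = degree_product(g)
        assert all(s == 3.0 for s in t.scores.values())

    def test_triangle(self, triangle):
        assert all(s == 4.0 for s in degree_product(triangle).scores.values())

    def test_theta_zero_flattens(self, barbell3):
        t = degree_product(barbell3, theta=0.0)
        assert all(s == 1.0 for s in t.scores.values())


# -- bridgeness ----------------------------------------------------------


class TestBridgeness:
    def test_barbell_bridge(self, barbell3):
        t = bridgeness(barbell3)
        assert t[barbell3.metadata["bridge"]] == pytest.approx(1.5)
        # clique-internal edges: S_x = S_y = S_e = 3
        assert t[("1", "2")] == pytest.approx(1.0)

    def test_isolated_edge(self):
        t = bridgeness(Graph([("a", "b")]))
        assert t[("a", "b")] == pytest.approx(1.0)

    @pytest.mark.parametrize("n,seed", [(6, 0), (8, 1), (10, 2), (10, 3)])
    def test_matches_brute_force_clique_enumeration(self, n, seed):
        g = _random_connected_graph(n, seed)
        t = bridgeness(g)
        node_best, edge_best = bf_clique_sizes(g)
        for u, v in g.edges:
            expected = math.sqrt(node_best[u] * node_best[v]) / edge_best[(u, v)]
            assert t[(u, v)] == pytest.approx(expected)

    def test_timeout_raises(self):
        g = Graph(((str(u), str(v))
                   for u, v in nx.gnp_random_graph(60, 0.6, seed=0).edges))
        with pytest.raises(CliqueTimeoutError):
            bridgeness(g, timeout=0.0)


# -- diffusion importance ------------------------------------------------


class TestDiffusionImportance:
    def test_isolated_edge_scores_zero(self):
        assert diffusion_importance(Graph([("a", "b")]))[("a", "b")] == 0.0

    def test_triangle_edges_score_zero(self, triangle):
        assert all(s == 0.0
                   for s in diffusion_importance(triangle).scores.values())

    def test_barbell_bridge(self, barbell3):
        t = diffusion_importance(barbell3)
        assert t[barbell3.metadata["bridge"]] == pytest.approx(2.0)


# -- topological overlap -------------------------------------------------


class TestTopologicalOverlap:
    def test_triangle_edge_full_overlap(self, triangle):
        assert all(s == pytest.approx(1.0)
                   for s in topological_overlap(triangle).scores.values())

    def test_isolated_edge_zero_by_convention(self):
        assert topological_overlap(Graph([("a", "b")]))[("a", "b")] == 0.0

    def test_barbell_bridge_no_common_neighbors(self, barbell3):
        t = topological_overlap(barbell3)
        assert t[barbell3.metadata["bridge"]] == 0.0


# -- ERW-Kpath -----------------------------------------------------------


class TestErwKpath:
    def test_single_edge_every_walk_crosses_it(self):
        t = erw_kpath(Graph([("a", "b")]), k=1, rho=500, seed=0)
        assert t[("a", "b")] == pytest.approx(1.0)

    def test_path_graph_symmetry_within_monte_carlo_error(self, path3):
        rho = 20000
        t = erw_kpath(path3, k=20, rho=rho, seed=1)
        a, b = t[("a", "b")], t[("b", "c")]
        sigma = math.sqrt(max(a, b) / rho)  # per-walk counts are 0/1 here
        assert abs(a - b) < 3 * sigma

    def test_total_traversals_bounded_by_walk_length(self, barbell3):
        k, rho = 4, 300
        t = erw_kpath(barbell3, k=k, rho=rho, seed=2)
        assert sum(t.scores.values()) * rho <= k * rho + 1e-9

    def test_estimates_tighten_as_rho_grows(self, path3):
        spread = []
        for rho in (200, 3200):
            vals = [erw_kpath(path3, k=20, rho=rho, seed=s)[("a", "b")]
                    for s in range(8)]
            spread.append(np.std(vals))
        # sigma ~ 1/sqrt(rho): 16x walks -> ~4x tighter, allow slack
        assert spread[1] < spread[0] / 2

    def test_same_seed_identical(self, barbell3):
        t1 = erw_kpath(barbell3, k=20, rho=100, seed=7)
        t2 = erw_kpath(barbell3, k=20, rho=100, seed=7)
        assert t1.scores == t2.scores


# -- dispatch ------------------------------------------------------------


class TestScoreMethod:
    def test_dispatch_records_params(self, triangle):
        t = score_method(triangle, "degree_product", theta=1.0)
        assert t.method == "degree_product"
        assert all(s == 4.0 for s in t.scores.values())

    def test_kpath_dispatch_deterministic(self, barbell3):
        t1 = score_method(barbell3, "kpath", k=20, rho=50, seed=1)
        t2 = score_method(barbell3, "kpath", k=20, rho=50, seed=1)
        assert t1.scores == t2.scores

    def test_unknown_method_lists_valid_names(self, triangle):
        with pytest.raises(ValueError, match="betweenness"):
            score_method(triangle, "pagerank")

    def test_all_methods_endpoint_symmetric_nonnegative(self, barbell3):
        for name in ("le", "betweenness", "degree_product", "bridgeness",
                     "diffusion", "overlap", "kpath"):
            kwargs = {"n_restarts": 3} if name == "le" else {}
            t = score_method(barbell3, name, **kwargs)
            assert set(t.scores) == set(barbell3.edges)
            assert all(s >= 0 for s in t.scores.values())
            u, v = barbell3.edges[0]
            assert t[(v, u)] == t[(u, v)]
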