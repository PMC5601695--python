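import math
from collections import deque

import numpy as np
import pytest

from brcapath.coexpression import (
    CoexpressionNetwork,
    CorrelationMatrix,
    centrality_comparison,
    pair_counts,
    pearson_matrix,
    threshold_network,
    topology_summary,
)
from brcapath.exceptions import InputError, ParameterError
from brcapath.io import ExpressionMatrix


def _expr_from_rows(rows, subtype="LA"):
    genes = [f"g{i}" for i in range(len(rows))]
    n = len(rows[0])
    samples = [f"s{i}" for i in range(n)]
    labels = {s: subtype for s in samples}
    return ExpressionMatrix(genes, samples, np.array(rows, float), labels)


def _corr(genes, pairs, subtype="LA"):
    """Correlation matrix from explicit off-diagonal entries."""
    n = len(genes)
    R = np.eye(n)
    for (i, j), r in pairs.items():
        R[i, j] = R[j, i] = r
    return CorrelationMatrix(genes=list(genes), R=R, subtype=subtype)


def _net(edges, nodes):
    e = {}
    for a, b in edges:
        key = (a, b) if a <= b else (b, a)
        e[key] = 1.0
    return CoexpressionNetwork(nodes=list(nodes), edges=e, subtype="LA", threshold=0.5)


class TestPearsonMatrix:
    def test_perfect_linear_relations(self):
        x = [1.0, 2, 3, 4]
        expr = _expr_from_rows([x, [2 * v + 1 for v in x], [-v for v in x]])
        corr = pearson_matrix(expr, expr.genes, "LA")
        assert corr.R[0, 1] == pytest.approx(1.0)
        assert corr.R[0, 2] == pytest.approx(-1.0)

    def test_hand_computed_r(self):
        expr = _expr_from_rows([[1, 2, 3, 4], [1, 3, 2, 4]])
        corr = pearson_matrix(expr, expr.genes, "LA")
        assert corr.R[0, 1] == pytest.approx(0.8, abs=1e-12)

    def test_zero_variance_gene_flagged_r_zero(self):
        expr = _expr_from_rows([[1, 2, 3, 4], [5, 5, 5, 5]])
        corr = pearson_matrix(expr, expr.genes, "LA")
        assert corr.degenerate_genes == ["g1"]
        assert np.all(corr.R[1, :] == 0)

    def test_small_stratum_rejected(self):
        expr = _expr_from_rows([[1, 2], [2, 1]])
        with pytest.raises(InputError):
            pearson_matrix(expr, expr.genes, "LA")


class TestThresholdNetwork:
    def test_strict_rule(self):
        corr = _corr(["a", "b", "c"], {(0, 1): 0.6, (0, 2): 0.4, (1, 2): -0.7})
        net = threshold_network(corr, 0.5)
        assert set(net.edges) == {("a", "b"), ("b", "c")}
        assert net.edges[("b", "c")] == pytest.approx(-0.7)

    def test_boundary_inclusive_vs_strict(self):
        corr = _corr(["a", "b"], {(0, 1): 0.5})
        assert threshold_network(corr, 0.5).edges == {}
        assert set(threshold_network(corr, 0.5, inclusive=True).edges) == {("a", "b")}

    def test_matches_bruteforce_double_loop(self):
        rng = np.random.default_rng(4)
        expr = _expr_from_rows(rng.normal(size=(20, 30)))
        corr = pearson_matrix(expr, expr.genes, "LA")
        net = threshold_network(corr, 0.3)
        expected = set()
        for i in range(20):
            for j in range(i + 1, 20):
                if abs(corr.R[i, j]) > 0.3:
                    expected.add(tuple(sorted((corr.genes[i], corr.genes[j]))))
        assert set(net.edges) == expected

    def test_threshold_domain(self):
        corr = _corr(["a", "b"], {(0, 1): 0.5})
        with pytest.raises(ParameterError):
            threshold_network(corr, 1.0)


class TestPairCounts:
    def test_hand_counts(self):
        corr = _corr(["a", "b", "c"], {(0, 1): 0.55, (0, 2): -0.65, (1, 2): 0.95})
        counts = pair_counts(corr)
        assert [counts[t] for t in (0.5, 0.6, 0.7, 0.8, 0.9)] == [3, 2, 1, 1, 1]

    def test_all_zero_matrix(self):
        corr = _corr(["a", "b", "c"], {})
        assert all(v == 0 for v in pair_counts(corr).values())

    def test_monotone_and_consistent_with_inclusive_network(self):
        rng = np.random.default_rng(9)
        expr = _expr_from_rows(rng.normal(size=(15, 10)))
        corr = pearson_matrix(expr, expr.genes, "LA")
        counts = pair_counts(corr)
        vals = [counts[t] for t in sorted(counts)]
        assert vals == sorted(vals, reverse=True)
        for t, c in counts.items():
            assert len(threshold_network(corr, t, inclusive=True).edges) == c


def _oracle_topology(net):
    """Brute-force BFS + neighbor-intersection reference implementation."""
    adj = {n: set() for n in net.nodes}
    for a, b in net.edges:
        adj[a].add(b)
        adj[b].add(a)
    out = {}
    for n in net.nodes:
        # BFS distances
        dist = {n: 0}
        dq = deque([n])
        while dq:
            u = dq.popleft()
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    dq.append(v)
        others = {v: d for v, d in dist.items() if v != n}
        aspl = sum(others.values()) / len(others) if others else 0.0
        clos = len(others) / sum(others.values()) if others else 0.0
        ratios = []
        for m in net.nodes:
            if m == n:
                continue
            shared = adj[n] & adj[m]
            if not shared:
                continue
            j = len(shared) + (1 if m in adj[n] else 0)
            ratios.append(j / len(adj[n]))
        tc = sum(ratios) / len(ratios) if ratios else 0.0
        out[n] = (len(adj[n]), aspl, clos, tc)
    return out


class TestTopologySummary:
    def test_path_graph_hand_values(self):
        net = _net([("a", "b"), ("b", "c")], ["a", "b", "c"])
        topo = topology_summary(net)
        assert topo.closeness["b"] == pytest.approx(1.0)
        assert topo.closeness["a"] == pytest.approx(2 / 3)
        assert topo.avg_shortest_path["a"] == pytest.approx(1.5)
        assert topo.avg_shortest_path["b"] == pytest.approx(1.0)

    def test_four_cycle_topological_coefficient(self):
        net = _net([("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")],
                   ["a", "b", "c", "d"])
        topo = topology_summary(net)
        for n in "abcd":
            assert topo.topological_coefficient[n] == pytest.approx(1.0)

    def test_star_graph(self):
        leaves = [f"l{i}" for i in range(4)]
        net = _net([("hub", l) for l in leaves], ["hub"] + leaves)
        topo = topology_summary(net)
        assert topo.topological_coefficient["hub"] == 0.0
        for l in leaves:
            assert topo.topological_coefficient[l] == pytest.approx(1.0)
        assert topo.closeness["hub"] == pytest.approx(1.0)

    def test_isolated_node_conventions(self):
        net = _net([("a", "b")], ["a", "b", "z"])
        topo = topology_summary(net)
        assert topo.isolated_nodes == ["z"]
        assert topo.closeness["z"] == 0.0 and topo.avg_shortest_path["z"] == 0.0

    def test_degree_sums_to_twice_edges_and_ranges(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            n = int(rng.integers(2, 25))
            nodes = [f"n{i}" for i in range(n)]
            edges = [
                (nodes[i], nodes[j])
                for i in range(n) for j in range(i + 1, n)
                if rng.random() < 0.2
            ]
            net = _net(edges, nodes)
            topo = topology_summary(net)
            assert sum(topo.degree.values()) == 2 * len(net.edges)
            for d in (topo.closeness, topo.topological_coefficient):
                assert all(0.0 <= v <= 1.0 + 1e-12 for v in d.values())

    def test_matches_bruteforce_oracle_on_random_graphs(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            n = int(rng.integers(2, 31))
            nodes = [f"n{i}" for i in range(n)]
            p = rng.uniform(0.05, 0.5)
            edges = [
                (nodes[i], nodes[j])
                for i in range(n) for j in range(i + 1, n)
                if rng.random() < p
            ]
            net = _net(edges, nodes)
            topo = topology_summary(net)
            oracle = _oracle_topology(net)
            for node, (deg, aspl, clos, tc) in oracle.items():
                assert topo.degree[node] == deg
                assert topo.avg_shortest_path[node] == pytest.approx(aspl)
                assert topo.closeness[node] == pytest.approx(clos)
                assert topo.topological_coefficient[node] == pytest.approx(tc)


class TestCentralityComparison:
    def test_uniform_degrees(self):
        nodes = [f"n{i}" for i in range(11)]
        edges = [(a, b) for i, a in enumerate(nodes) for b in nodes[i + 1:]]
        net = _net(edges, nodes)  # complete graph: degree 10 everywhere
        topo = topology_summary(net)
        cc = centrality_comparison(topo, {"n0", "n1"})
        assert cc.core_mean_log10_degree == pytest.approx(1.0)
        assert cc.all_mean_log10_degree == pytest.approx(1.0)
        assert cc.all_sd_log10_degree == pytest.approx(0.0)

    def test_log_degree_arithmetic(self):
        from brcapath.coexpression import TopologySummary

        topo = TopologySummary(
            degree={"a": 1, "b": 10, "c": 100},
            avg_shortest_path={}, closeness={}, topological_coefficient={},
            isolated_nodes=[],
        )
        cc = centrality_comparison(topo, set())
        assert cc.all_mean_log10_degree == pytest.approx(1.0)
        assert cc.all_sd_log10_degree == pytest.approx(1.0)
        assert cc.core_mean_log10_degree is None

    def test_planted_hubs_exceed_average(self):
        rng = np.random.default_rng(6)
        nodes = [f"n{i}" for i in range(40)]
        hubs = set(nodes[:5])
        edges = set()
        for h in hubs:  # hubs wired to most nodes
            for other in nodes:
                if other != h and rng.random() < 0.8:
                    edges.add(tuple(sorted((h, other))))
        for i in range(5, 40):  # sparse background
            j = int(rng.integers(5, 40))
            if j != i:
                edges.add(tuple(sorted((nodes[i], nodes[j]))))
        topo = topology_summary(_net(sorted(edges), nodes))
        cc = centrality_comparison(topo, hubs)
        assert cc.core_mean_log10_degree > cc.all_mean_log10_degree
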