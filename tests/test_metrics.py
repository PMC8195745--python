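"""Network summary statistics against closed forms and brute-force oracles."""

import math
from collections import defaultdict

import networkx as nx
import numpy as np
import pytest

from rhizonet.containers import SignedNetwork
from rhizonet.metrics import (
    betweenness, compare_networks, degree_stats, detect_modules,
    keystone_otus, metrics_report, sign_ratio, taxon_composition,
)


def net(edges, name="n"):
    return SignedNetwork(name=name, edges=dict(edges))


def random_signed_network(rng, n_nodes, n_edges):
    nodes = [f"v{i}" for i in range(n_nodes)]
    edges = {}
    # spanning path first so every node is an endpoint
    for i in range(n_nodes - 1):
        a, b = sorted((nodes[i], nodes[i + 1]))
        edges[(a, b)] = float(rng.uniform(0.1, 1)) * \
            (1 if rng.random() > 0.2 else -1)
    while len(edges) < n_edges:
        i, j = rng.choice(n_nodes, 2, replace=False)
        a, b = sorted((nodes[i], nodes[j]))
        edges.setdefault((a, b), float(rng.uniform(0.1, 1)))
    return net(edges)


def brute_force_betweenness(g):
    """All-pairs shortest-path enumeration; even split over ties.

    Independent of networkx's accumulation algorithm: enumerates every
    shortest path explicitly.
    """
    node_b = {v: 0.0 for v in g.nodes}
    edge_b = {tuple(sorted(e)): 0.0 for e in g.edges}
    nodes = sorted(g.nodes)
    for i, s in enumerate(nodes):
        for t in nodes[i + 1:]:
            if not nx.has_path(g, s, t):
                continue
            paths = list(nx.all_shortest_paths(g, s, t))
            w = 1.0 / len(paths)
            for path in paths:
                for v in path[1:-1]:
                    node_b[v] += w
                for a, b in zip(path, path[1:]):
                    edge_b[tuple(sorted((a, b)))] += w
    return node_b, edge_b


class TestDegreeStats:
    @pytest.mark.parametrize("n_nodes,n_edges,expected", [
        (573, 1673, 5.8),   # cleaned intercropped wheat network
        (451, 1189, 5.3),   # cleaned intercropped pea network
    ])
    def test_mean_degree_matches_reported_networks(self, rng, n_nodes,
                                                   n_edges, expected):
        network = random_signed_network(rng, n_nodes, n_edges)
        n, e, mean_deg = degree_stats(network)
        assert (n, e) == (n_nodes, n_edges)
        assert round(mean_deg, 1) == expected

    def test_empty_network(self):
        assert degree_stats(net({})) == (0, 0, 0.0)


class TestBetweenness:
    def test_path_center(self):
        node_b, _, _, _ = betweenness(net({("A", "B"): 1, ("B", "C"): 1}))
        assert node_b == {"A": 0.0, "B": 1.0, "C": 0.0}

    def test_triangle_all_zero(self):
        node_b, _, _, _ = betweenness(
            net({("A", "B"): 1, ("B", "C"): 1, ("A", "C"): 1}))
        assert all(v == 0 for v in node_b.values())

    def test_star_center_counts_leaf_pairs(self):
        edges = {("hub", f"l{i}"): 1.0 for i in range(4)}
        node_b, _, _, _ = betweenness(net(edges))
        assert node_b["hub"] == 6.0  # C(4, 2) leaf pairs

    def test_matches_brute_force_on_small_graphs(self, rng):
        for _ in range(25):
            n_nodes = int(rng.integers(4, 13))
            max_edges = n_nodes * (n_nodes - 1) // 2
            n_edges = int(rng.integers(n_nodes - 1, max_edges + 1))
            network = random_signed_network(rng, n_nodes, n_edges)
            node_b, edge_b, _, _ = betweenness(network)
            ref_n, ref_e = brute_force_betweenness(network.to_networkx())
            for v in ref_n:
                assert node_b[v] == pytest.approx(ref_n[v], abs=1e-9)
            for e in ref_e:
                assert edge_b[e] == pytest.approx(ref_e[e], abs=1e-9)


class TestSignRatio:
    @pytest.mark.parametrize("pos,neg,expected", [
        (1462, 211, 6.9),   # wheat network sign counts
        (1112, 77, 14.4),   # pea network sign counts
    ])
    def test_reported_sign_ratios(self, rng, pos, neg, expected):
        # a path network carrying exactly the reported sign counts
        edges = {(f"n{i:04d}", f"n{i + 1:04d}"): (0.5 if i < pos else -0.5)
                 for i in range(pos + neg)}
        assert round(sign_ratio(net(edges)), 1) == expected

    def test_no_negatives_flagged_infinite(self):
        network = net({("A", "B"): 0.5, ("C", "D"): 0.2})
        assert math.isinf(sign_ratio(network))


class TestKeystones:
    def test_single_hub_detected(self):
        edges = {("hub", f"l{i}"): 1.0 for i in range(20)}
        edges.update({(f"l{2 * i}", f"l{2 * i + 1}"): 1.0 for i in range(5)})
        out = keystone_otus(net(edges), k=3.0)
        assert [o for o, _ in out] == ["hub"]

    def test_regular_graph_has_none(self):
        square = {("A", "B"): 1, ("B", "C"): 1, ("C", "D"): 1, ("A", "D"): 1}
        assert keystone_otus(net(square), k=3.0) == []

    def test_k_zero_equals_above_mean_enumeration(self, rng):
        network = random_signed_network(rng, 15, 25)
        g = network.to_networkx()
        degs = dict(g.degree())
        mean = np.mean(list(degs.values()))
        expected = {v for v, d in degs.items() if d > mean}
        got = {o for o, _ in keystone_otus(network, k=0.0)}
        assert got == expected

    def test_needs_three_nodes(self):
        with pytest.raises(ValueError):
            keystone_otus(net({("A", "B"): 1.0}))


class TestModules:
    def test_two_cliques_two_modules(self):
        edges = {}
        for grp, names in enumerate([list("ABC"), list("XYZ")]):
            for i in range(3):
                for j in range(i + 1, 3):
                    edges[(names[i], names[j])] = 1.0
        edges[("C", "X")] = 0.1  # weak bridge keeps the graph connected
        partition, q = detect_modules(net(edges), seed=0)
        assert len(set(partition.values())) == 2
        assert partition["A"] == partition["B"] == partition["C"]
        assert partition["X"] == partition["Y"] == partition["Z"]
        assert q > 0

    def test_single_edge_modularity_by_direct_formula(self):
        partition, q = detect_modules(net({("A", "B"): 0.7}), seed=0)
        # one community of both nodes: Q = e_c/m - (d_c/2m)^2 = 1 - 1 = 0
        assert set(partition) == {"A", "B"}
        assert q == pytest.approx(0.0, abs=1e-12)

    def test_empty_network(self):
        assert detect_modules(net({}), seed=0) == ({}, 0.0)

    def test_partition_covers_all_nodes(self, rng):
        network = random_signed_network(rng, 20, 35)
        partition, _ = detect_modules(network, seed=0)
        assert set(partition) == network.nodes


class TestTaxonComposition:
    def test_single_phylum(self):
        network = net({("A", "B"): 1.0})
        assert taxon_composition(network, {"A": "Px", "B": "Px"}) == {"Px": 1.0}

    def test_half_split_and_unassigned(self):
        network = net({("A", "B"): 1.0, ("C", "D"): 1.0})
        out = taxon_composition(network, {"A": "Px", "B": "Px"})
        assert out == {"Px": 0.5, "Unassigned": 0.5}

    def test_matches_direct_count(self, rng):
        network = random_signed_network(rng, 12, 18)
        taxonomy = {v: f"P{int(rng.integers(0, 3))}"
                    for v in sorted(network.nodes)}
        out = taxon_composition(network, taxonomy)
        counts = defaultdict(int)
        for v in network.nodes:
            counts[taxonomy[v]] += 1
        for taxon, frac in out.items():
            assert frac == pytest.approx(counts[taxon] / network.n_nodes)
        assert sum(out.values()) == pytest.approx(1.0)


class TestCompareNetworks:
    def test_identical_networks_tied_or_p_one(self, rng):
        a = random_signed_network(rng, 10, 16)
        rep = compare_networks(a, a)
        for metric, p in rep.metric_pvalues.items():
            assert p > 0.97 or rep.tied_flags[metric]

    def test_forced_ordering(self):
        star = {("h", f"l{i}"): 1.0 for i in range(10)}
        path = {(f"p{i}", f"p{i + 1}"): 1.0 for i in range(3)}
        rep = compare_networks(net(star), net(path))
        assert rep.directions["node_betweenness"] == "a > b"

    def test_degree_pvalue_matches_direct_ranksum(self, rng):
        from scipy import stats

        for _ in range(5):
            a = random_signed_network(rng, 12, 20)
            b = random_signed_network(rng, 9, 14)
            rep = compare_networks(a, b)
            da = [d for _, d in a.to_networkx().degree()]
            db = [d for _, d in b.to_networkx().degree()]
            ref = stats.mannwhitneyu(da, db, alternative="two-sided").pvalue
            assert rep.metric_pvalues["degree"] == pytest.approx(ref, abs=1e-8)


class TestMetricsReport:
    def test_internal_consistency_and_relabel_invariance(self, rng):
        network = random_signed_network(rng, 14, 22)
        rep = metrics_report(network, taxonomy={v: "P" for v in network.nodes})
        assert rep.n_edges == rep.n_positive + rep.n_negative
        assert rep.mean_degree == pytest.approx(2 * rep.n_edges / rep.n_nodes)
        assert sum(rep.taxon_composition.values()) == pytest.approx(1.0)
        # relabel every node: scalar metrics must not move
        mapping = {v: f"relabelled_{v}" for v in network.nodes}
        relabelled = net({(mapping[a], mapping[b]): w
                          for (a, b), w in network.edges.items()})
        rep2 = metrics_report(relabelled,
                              taxonomy={v: "P" for v in relabelled.nodes})
        assert rep2.mean_degree == pytest.approx(rep.mean_degree)
        assert rep2.mean_node_betweenness == pytest.approx(rep.mean_node_betweenness)
        assert rep2.mean_edge_betweenness == pytest.approx(rep.mean_edge_betweenness)
        assert rep2.pos_neg_ratio == pytest.approx(rep.pos_neg_ratio)
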