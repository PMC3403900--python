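import networkx as nx
import numpy as np
import pytest

import coregrn as cg
from coregrn import network_analysis as na


def betweenness_oracle(g):
    """Exhaustive shortest-path enumeration; ties split equally."""
    bet = {e: 0.0 for e in g.edges()}
    for s in g.nodes():
        for t in g.nodes():
            if s == t:
                continue
            try:
                paths = list(nx.all_shortest_paths(g, s, t))
            except nx.NetworkXNoPath:
                continue
            for path in paths:
                for u, v in zip(path, path[1:]):
                    bet[(u, v)] += 1.0 / len(paths)
    return bet


class TestLargestComponent:
    def test_connected_network_is_identity(self):
        g = nx.cycle_graph(5, create_using=nx.DiGraph)
        assert set(na.largest_component(g).nodes()) == set(g.nodes())

    def test_picks_bigger_component(self):
        g = nx.DiGraph()
        g.add_edges_from((i, i + 1) for i in range(7))  # 8 nodes
        g.add_edges_from([(100, 101), (101, 102)])  # 3 nodes
        assert set(na.largest_component(g).nodes()) == set(range(8))

    def test_tie_broken_by_smallest_node_id(self):
        g = nx.DiGraph([("b", "c"), ("a", "d")])
        assert set(na.largest_component(g).nodes()) == {"a", "d"}

    def test_preserves_network_type_and_cutoffs(self):
        graph = nx.DiGraph([("TF1", "g1")])
        graph.add_node("TF1", entity_class="TF")
        net = cg.RegulatoryNetwork(graph=graph, class_cutoffs={"TF": 0.5, "miRNA": 0.3})
        out = na.largest_component(net)
        assert isinstance(out, cg.RegulatoryNetwork)
        assert out.class_cutoffs == {"TF": 0.5, "miRNA": 0.3}


class TestDetectModules:
    def test_two_cliques_joined_by_bridge(self):
        g = nx.disjoint_union(nx.complete_graph(10), nx.complete_graph(10))
        g.add_edge(0, 10)
        part = na.detect_modules(g)
        assert part.n_modules == 2
        groups = {}
        for node, m in part.assignment.items():
            groups.setdefault(m, set()).add(node)
        assert set(frozenset(v) for v in groups.values()) == {
            frozenset(range(10)),
            frozenset(range(10, 20)),
        }

    def test_recovers_planted_partition(self):
        from sklearn.metrics import adjusted_rand_score

        g, labels = cg.generate_modular_graph([30, 30, 30], 0.5, 0.01, seed=5)
        part = na.detect_modules(g)
        nodes = sorted(labels)
        ari = adjusted_rand_score(
            [labels[n] for n in nodes], [part.assignment[n] for n in nodes]
        )
        assert ari > 0.8

    def test_complete_graph_is_one_module(self):
        part = na.detect_modules(nx.complete_graph(8))
        assert part.n_modules == 1

    def test_single_node(self):
        g = nx.DiGraph()
        g.add_node("x")
        part = na.detect_modules(g)
        assert part.assignment == {"x": 1}

    def test_modularity_at_least_trivial_partition(self):
        g, _ = cg.generate_modular_graph([20, 20], 0.4, 0.05, seed=2)
        part = na.detect_modules(g)
        assert part.modularity >= 0.0  # one-module partition has modularity 0

    def test_coverage_and_sizes_consistent(self):
        g, _ = cg.generate_modular_graph([15, 10, 5], 0.6, 0.02, seed=1)
        part = na.detect_modules(g)
        assert sum(part.sizes) == g.number_of_nodes()
        assert part.sizes == sorted(part.sizes, reverse=True)
        assert part.coverage(part.n_modules) == pytest.approx(1.0)


class TestEdgeBetweenness:
    def test_two_edge_path(self):
        g = nx.DiGraph([("A", "B"), ("B", "C")])
        bet = na.edge_betweenness(g)
        assert bet[("A", "B")] == pytest.approx(2.0)
        assert bet[("B", "C")] == pytest.approx(2.0)

    def test_directed_triangle_symmetric(self):
        g = nx.DiGraph([("A", "B"), ("B", "C"), ("C", "A")])
        values = set(na.edge_betweenness(g).values())
        assert len(values) == 1

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_enumeration_oracle(self, seed):
        g = nx.gnp_random_graph(8, 0.3, seed=seed, directed=True)
        bet = na.edge_betweenness(g)
        oracle = betweenness_oracle(g)
        for e in g.edges():
            assert bet[e] == pytest.approx(oracle[e], abs=1e-9)

    def test_total_betweenness_equals_sum_of_path_lengths(self):
        g = nx.gnp_random_graph(10, 0.25, seed=4, directed=True)
        bet = na.edge_betweenness(g)
        lengths = dict(nx.all_pairs_shortest_path_length(g))
        expected = sum(
            d for s, dd in lengths.items() for t, d in dd.items() if s != t
        )
        assert sum(bet.values()) == pytest.approx(expected, abs=1e-9)

    def test_undirected_mode(self):
        g = nx.DiGraph([("A", "B"), ("B", "C")])
        bet = na.edge_betweenness(g, directed=False)
        # undirected pairs: AB, AC, BC each counted once
        assert bet[("A", "B")] == pytest.approx(2.0)


class TestExtractCore:
    def chain_graph(self, n_edges):
        g = nx.DiGraph()
        g.add_edges_from((i, i + 1) for i in range(n_edges))
        return g

    def test_order_statistics_on_long_path(self):
        # 200-edge directed path: edge i has betweenness (i+1)(200-i); the
        # top pair sits strictly above the interpolated 99% quantile
        g = self.chain_graph(200)
        core = na.extract_core(g, quantile=0.99)
        assert core.n_edges == 2

    def test_quantile_zero_drops_only_minimum(self):
        g = self.chain_graph(10)
        bet = na.edge_betweenness(g)
        core = na.extract_core(g, quantile=0.0)
        expected = sum(1 for v in bet.values() if v > min(bet.values()))
        assert core.n_edges == expected

    def test_quantile_near_one_empties_core(self):
        g = self.chain_graph(10)
        core = na.extract_core(g, quantile=1.0 - 1e-12)
        assert core.n_edges == 0

    def test_invalid_quantile_rejected(self):
        g = self.chain_graph(5)
        for q in (-0.1, 1.0, 2.0):
            with pytest.raises(ValueError):
                na.extract_core(g, quantile=q)

    def test_betweenness_fraction_dominates_edge_fraction(self):
        for seed in range(5):
            g = cg.generate_scalefree_digraph(300, 900, seed=seed)
            core = na.extract_core(g, quantile=0.9)
            assert core.betweenness_fraction >= core.edge_fraction

    def test_edge_fraction_near_one_percent_on_scalefree_grn(self):
        g = cg.generate_scalefree_digraph(1700, 4200, seed=3)
        core = na.extract_core(g, quantile=0.99)
        assert 0.005 <= core.edge_fraction <= 0.015

    def test_core_deletion_preserves_weak_connectivity(self):
        """Removing top-1% betweenness edges keeps the synthetic GRN connected
        in >= 90% of seeds."""
        intact = 0
        for seed in range(10):
            g = cg.generate_scalefree_digraph(800, 2000, seed=seed)
            before = nx.number_weakly_connected_components(g)
            core = na.extract_core(g, quantile=0.99)
            pruned = g.copy()
            pruned.remove_edges_from(core.graph.edges())
            intact += nx.number_weakly_connected_components(pruned) == before
        assert intact >= 9

    def test_non_regulator_endpoint_warning(self, caplog):
        g = nx.DiGraph()
        g.add_edges_from((i, i + 1) for i in range(20))
        nx.set_node_attributes(g, "gene", "entity_class")
        with caplog.at_level("WARNING"):
            core = na.extract_core(g, quantile=0.5)
        assert core.non_regulator_nodes  # genes in the core are flagged
        assert any("non-regulator" in r.message for r in caplog.records)


class TestCountLoops:
    def test_canonical_feedforward(self):
        g = nx.DiGraph([("A", "B"), ("B", "C"), ("A", "C")])
        assert na.count_loops(g) == (1, 0)

    def test_two_cycle(self):
        g = nx.DiGraph([("A", "B"), ("B", "A")])
        assert na.count_loops(g) == (0, 1)

    def test_three_cycle(self):
        g = nx.DiGraph([("A", "B"), ("B", "C"), ("C", "A")])
        assert na.count_loops(g) == (0, 1)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_enumeration_oracle(self, seed):
        from itertools import combinations, permutations

        g = nx.gnp_random_graph(10, 0.25, seed=seed, directed=True)
        ffl = sum(
            1
            for a, b, c in permutations(g.nodes(), 3)
            if g.has_edge(a, b) and g.has_edge(b, c) and g.has_edge(a, c)
        )
        fb2 = sum(
            1 for a, b in combinations(g.nodes(), 2)
            if g.has_edge(a, b) and g.has_edge(b, a)
        )
        fb3 = (
            sum(
                1
                for a, b, c in permutations(g.nodes(), 3)
                if g.has_edge(a, b) and g.has_edge(b, c) and g.has_edge(c, a)
            )
            // 3
        )
        assert na.count_loops(g) == (ffl, fb2 + fb3)
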