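import networkx as nx
import pytest

from pepfam.graph import (
    batch_components,
    build_graph,
    component_threshold_prune,
    drop_singletons_and_pendants,
    prune_k_best,
    select_k,
    split_components,
)
from pepfam.similarity import SrvHit

from .conftest import random_graph
from .oracles import select_k_oracle


def _hit(q, s, srv, qcov=1.0, scov=1.0):
    return SrvHit(q, s, bit_score=srv * 50, srv=srv, q_coverage=qcov, s_coverage=scov, e_value=1e-9)


class TestBuildGraph:
    def test_reciprocal_average(self):
        g = build_graph([_hit("a", "b", 0.8), _hit("b", "a", 0.6)])
        assert g["a"]["b"]["weight"] == pytest.approx(0.7)

    def test_srv_below_limit_dropped(self):
        g = build_graph([_hit("a", "b", 0.29), _hit("b", "a", 0.29)])
        assert g.number_of_edges() == 0
        g = build_graph([_hit("a", "b", 0.3), _hit("b", "a", 0.3)])
        assert g.number_of_edges() == 1

    def test_mutual_coverage_requires_both_sides(self):
        g = build_graph([_hit("a", "b", 0.9, qcov=0.65, scov=0.95)])
        assert g.number_of_edges() == 0
        g = build_graph([_hit("a", "b", 0.9, qcov=0.70, scov=0.70)])
        assert g.number_of_edges() == 1
        g = build_graph([_hit("a", "b", 0.9, qcov=0.6999, scov=0.95)])
        assert g.number_of_edges() == 0

    def test_one_directional_hit_keeps_own_srv(self):
        g = build_graph([_hit("a", "b", 0.8), _hit("b", "a", 0.29)])
        assert g["a"]["b"]["weight"] == pytest.approx(0.8)

    def test_require_reciprocal_drops_unpaired(self):
        g = build_graph([_hit("a", "b", 0.8)], require_reciprocal=True)
        assert g.number_of_edges() == 0

    def test_universe_keeps_isolated_nodes(self):
        g = build_graph([_hit("a", "b", 0.8), _hit("b", "a", 0.8)], universe=["a", "b", "c"])
        assert set(g.nodes) == {"a", "b", "c"} and g.degree("c") == 0

    def test_weight_within_contributing_srv_bounds(self):
        g = build_graph([_hit("a", "b", 0.9), _hit("b", "a", 0.5)])
        w = g["a"]["b"]["weight"]
        assert 0.5 <= w <= 0.9


class TestDropSingletonsAndPendants:
    def test_path_interior_survives_single_pass(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=0.5)
        g.add_edge("b", "c", weight=0.5)
        pruned, report = drop_singletons_and_pendants(g)
        assert set(pruned.nodes) == {"b"}
        assert pruned.number_of_edges() == 0
        assert report.pendants == ["a", "c"] and report.singletons == []

    def test_triangle_unchanged(self):
        g = nx.Graph()
        for e in (("a", "b"), ("b", "c"), ("a", "c")):
            g.add_edge(*e, weight=0.5)
        pruned, report = drop_singletons_and_pendants(g)
        assert set(pruned.nodes) == {"a", "b", "c"} and pruned.number_of_edges() == 3
        assert report.pendants == [] and report.singletons == []

    def test_empty_graph_identity(self):
        pruned, report = drop_singletons_and_pendants(nx.Graph())
        assert pruned.number_of_nodes() == 0
        assert report.singletons == [] and report.pendants == []

    def test_isolated_nodes_reported_as_singletons(self):
        g = nx.Graph()
        g.add_node("solo")
        g.add_edge("a", "b", weight=0.4)
        g.add_edge("b", "c", weight=0.4)
        g.add_edge("a", "c", weight=0.4)
        _, report = drop_singletons_and_pendants(g)
        assert report.singletons == ["solo"]


class TestKBestPruning:
    def test_k_at_least_max_degree_is_identity(self, rng):
        g = random_graph(rng, 12)
        k = max(dict(g.degree()).values())
        pruned = prune_k_best(g, k)
        assert set(pruned.edges) == set(g.edges)

    def test_triangle_mutual_top1(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=0.9)
        g.add_edge("b", "c", weight=0.8)
        g.add_edge("a", "c", weight=0.4)
        pruned = prune_k_best(g, 1)
        assert set(map(frozenset, pruned.edges)) == {frozenset(("a", "b"))}

    def test_subgraph_monotonicity(self, rng):
        g = random_graph(rng, 15)
        for k in range(1, 6):
            pruned = prune_k_best(g, k)
            assert set(pruned.edges) <= set(g.edges)
            assert set(pruned.nodes) == set(g.nodes)

    def test_mutual_pairs_give_k_one(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=0.9)
        g.add_edge("c", "d", weight=0.8)
        assert select_k(g) == 1

    def test_equal_weight_star_needs_k_equal_leaves(self):
        g = nx.Graph()
        for leaf in "bcd":
            g.add_edge("a", leaf, weight=0.5)
        assert select_k(g) == 3

    def test_select_k_leaves_no_singleton(self, rng):
        g = random_graph(rng, 20)
        k = select_k(g)
        assert min(dict(prune_k_best(g, k).degree()).values()) >= 1
        if k > 1:
            assert min(dict(prune_k_best(g, k - 1).degree()).values()) == 0

    def test_select_k_matches_oracle_on_random_graphs(self, rng):
        for _ in range(40):
            n = int(rng.integers(4, 31))
            g = random_graph(rng, n, edge_prob=float(rng.uniform(0.1, 0.6)))
            assert select_k(g) == select_k_oracle(g)

    def test_degree_zero_precondition(self):
        g = nx.Graph()
        g.add_node("a")
        with pytest.raises(ValueError):
            select_k(g)


class TestComponents:
    def test_two_triangles(self):
        g = nx.Graph()
        for base in ("x", "y"):
            for e in (("1", "2"), ("2", "3"), ("1", "3")):
                g.add_edge(base + e[0], base + e[1], weight=0.5)
        comps = split_components(g)
        assert len(comps) == 2
        assert all(c.mean_degree == pytest.approx(2.0) for c in comps)
        assert all(c.mean_edge_weight == pytest.approx(0.5) for c in comps)

    def test_partition_property(self, rng):
        g = random_graph(rng, 18, edge_prob=0.12)
        comps = split_components(g)
        nodes = [n for c in comps for n in c.nodes]
        assert sorted(nodes) == sorted(g.nodes)
        assert len(nodes) == len(set(nodes))

    def test_empty_graph(self):
        assert split_components(nx.Graph()) == []


class TestComponentThresholdPrune:
    def test_uniform_weights_unchanged(self):
        g = nx.Graph()
        for e in (("a", "b"), ("b", "c"), ("a", "c")):
            g.add_edge(*e, weight=0.5)
        comp = split_components(g)[0]
        pruned = component_threshold_prune(comp)
        assert set(pruned.graph.edges) == set(comp.graph.edges)

    def test_bridge_between_triangles_removed(self):
        g = nx.Graph()
        for base in ("x", "y"):
            for e in (("1", "2"), ("2", "3"), ("1", "3")):
                g.add_edge(base + e[0], base + e[1], weight=0.9)
        g.add_edge("x1", "y1", weight=0.35)
        comp = split_components(g)[0]
        pruned = component_threshold_prune(comp)
        assert frozenset(("x1", "y1")) not in set(map(frozenset, pruned.graph.edges))
        assert len(split_components(pruned.graph)) == 2

    def test_no_node_isolated_and_subgraph(self, rng):
        for _ in range(10):
            g = random_graph(rng, 12, edge_prob=0.3)
            comp = split_components(g)[0]
            pruned = component_threshold_prune(comp)
            assert set(pruned.graph.edges) <= set(comp.graph.edges)
            if pruned.graph.number_of_nodes() > 1:
                assert min(dict(pruned.graph.degree()).values()) >= 1


class TestBatching:
    def test_single_component_single_batch(self, rng):
        g = random_graph(rng, 8)
        comps = split_components(g)
        batches = batch_components(comps)
        assert len(batches) == 1

    def test_identical_components_collapse_to_one_batch(self):
        g = nx.Graph()
        for base in ("p", "q", "r"):
            for e in (("1", "2"), ("2", "3"), ("1", "3")):
                g.add_edge(base + e[0], base + e[1], weight=0.5)
        batches = batch_components(split_components(g))
        assert len(batches) == 1 and len(batches[0].components) == 3

    def test_batches_partition_components(self, rng):
        g = random_graph(rng, 30, edge_prob=0.1)
        comps = split_components(g)
        batches = batch_components(comps)
        seen = [id(c) for b in batches for c in b.components]
        assert sorted(seen) == sorted(id(c) for c in comps)

    def test_empty_component_list_rejected(self):
        with pytest.raises(ValueError):
            batch_components([])
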