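"""Randomization enrichment: node sets, edge classes, links, giant components."""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pytest

import cinet
from cinet.io import AnnotationSet, DirectedLinkSet

from conftest import random_string_graph


def _ids(prefix, n):
    return [f"{prefix}{i:04d}" for i in range(n)]


class TestEnrichmentScore:
    def test_planted_feature_inside_group(self):
        # feature entirely inside a half-universe group: f_obs = 0.4 vs
        # null expectation 0.2 → score ≈ 1 (Jensen bias + MC error < 0.1)
        universe = _ids("N", 100)
        group = AnnotationSet("group", frozenset(universe[:50]))
        feature = AnnotationSet("feat", frozenset(universe[:20]))
        res = cinet.enrichment_score(universe, group, feature, R=10_000, seed=7)
        assert res.f_obs == pytest.approx(0.4)
        assert res.f_rand_mean == pytest.approx(0.2, abs=0.01)
        assert res.score == pytest.approx(1.0, abs=0.1)
        assert res.p_value <= 0.01

    def test_feature_equal_universe_is_exact_zero(self):
        universe = _ids("N", 30)
        group = AnnotationSet("group", frozenset(universe[:10]))
        feature = AnnotationSet("all", frozenset(universe))
        res = cinet.enrichment_score(universe, group, feature, R=50, seed=0)
        assert res.score == 0.0
        assert res.p_value == 1.0

    def test_null_features_center_on_zero(self):
        universe = _ids("N", 400)
        rng = np.random.default_rng(5)
        group = AnnotationSet("group", frozenset(rng.choice(universe, 150, replace=False)))
        scores = []
        for rep in range(50):
            feature = AnnotationSet(
                "rand", frozenset(rng.choice(universe, 150, replace=False))
            )
            scores.append(
                cinet.enrichment_score(universe, group, feature, R=400, seed=rep).score
            )
        scores = np.asarray(scores)
        se = scores.std(ddof=1) / np.sqrt(len(scores))
        assert abs(scores.mean()) < 3 * se

    def test_p_value_bounds(self):
        universe = _ids("N", 50)
        group = AnnotationSet("g", frozenset(universe[:25]))
        feature = AnnotationSet("f", frozenset(universe[:10]))
        res = cinet.enrichment_score(universe, group, feature, R=99, seed=1)
        assert 1 / 100 <= res.p_value <= 1.0

    def test_reproducible_for_identical_seed(self):
        universe = _ids("N", 60)
        group = AnnotationSet("g", frozenset(universe[:30]))
        feature = AnnotationSet("f", frozenset(universe[20:40]))
        a = cinet.enrichment_score(universe, group, feature, R=500, seed=9)
        b = cinet.enrichment_score(universe, group, feature, R=500, seed=9)
        assert a == b

    def test_empty_intersections_raise(self):
        universe = _ids("N", 10)
        inside = AnnotationSet("in", frozenset(universe[:5]))
        outside = AnnotationSet("out", frozenset({"absent"}))
        with pytest.raises(ValueError):
            cinet.enrichment_score(universe, outside, inside)
        with pytest.raises(ValueError):
            cinet.enrichment_score(universe, inside, outside)

    def test_zero_observed_overlap_stays_finite(self):
        universe = _ids("N", 40)
        group = AnnotationSet("g", frozenset(universe[:10]))
        feature = AnnotationSet("f", frozenset(universe[30:]))
        res = cinet.enrichment_score(universe, group, feature, R=200, seed=3)
        assert np.isfinite(res.score)
        assert res.score < 0  # depletion


class TestEdgeClassEnrichment:
    def test_marked_everything_is_null_identical(self):
        net = random_string_graph(12, 0.4, seed=0)
        marked = AnnotationSet("all", frozenset(net.nodes))
        res = cinet.edge_class_enrichment(net, marked, R=50, seed=0)
        assert res.classes["marked-marked"].observed == net.number_of_edges()
        for stats in res.classes.values():
            assert stats.log2_enrichment == 0.0
            assert stats.p_value == 1.0

    def test_path_single_marked_node_exact_null(self):
        # null over single-node markings of A–B–C: marked-unmarked counts
        # are {B: 2, A: 1, C: 1} → mean 4/3; marking B is enriched
        net = nx.path_graph(["A", "B", "C"])
        res = cinet.edge_class_enrichment(
            net, AnnotationSet("m", frozenset({"B"})), R=6000, seed=2
        )
        mu = res.classes["marked-unmarked"]
        assert mu.observed == 2
        assert mu.null_mean == pytest.approx(4 / 3, abs=0.05)
        assert mu.log2_enrichment > 0

    def test_planted_block_recovered(self):
        # dense block over the marked half vs sparse elsewhere
        rng = np.random.default_rng(8)
        nodes = _ids("B", 40)
        net = nx.Graph()
        net.add_nodes_from(nodes)
        block = nodes[:20]
        for a, b in itertools.combinations(block, 2):
            if rng.random() < 0.5:
                net.add_edge(a, b)
        for a, b in itertools.combinations(nodes, 2):
            if (a not in block or b not in block) and rng.random() < 0.05:
                net.add_edge(a, b)
        res = cinet.edge_class_enrichment(
            net, AnnotationSet("block", frozenset(block)), R=2000, seed=1
        )
        assert res.classes["marked-marked"].log2_enrichment > 0
        assert res.classes["unmarked-unmarked"].log2_enrichment < 0

    def test_class_counts_conserved_in_every_round(self):
        net = random_string_graph(15, 0.3, seed=4)
        marked = AnnotationSet("m", frozenset(sorted(net.nodes)[:5]))
        res = cinet.edge_class_enrichment(net, marked, R=300, seed=4)
        total = sum(stats.observed for stats in res.classes.values())
        assert total == res.n_edges == net.number_of_edges()
        null_total = sum(s.null_mean for s in res.classes.values())
        assert null_total == pytest.approx(net.number_of_edges())

    def test_edge_subset_restricts_the_statistic(self):
        net = nx.path_graph(["A", "B", "C", "D"])
        res = cinet.edge_class_enrichment(
            net,
            AnnotationSet("m", frozenset({"A", "B"})),
            R=50,
            seed=0,
            edge_subset=[("A", "B")],
        )
        assert res.n_edges == 1
        assert res.classes["marked-marked"].observed == 1

    def test_foreign_edge_subset_rejected(self):
        net = nx.path_graph(["A", "B", "C"])
        with pytest.raises(ValueError):
            cinet.edge_class_enrichment(
                net,
                AnnotationSet("m", frozenset({"A"})),
                R=10,
                seed=0,
                edge_subset=[("A", "C")],
            )

    def test_empty_marked_set_raises(self):
        net = nx.path_graph(["A", "B"])
        with pytest.raises(ValueError):
            cinet.edge_class_enrichment(net, AnnotationSet("m", frozenset({"Z"})), R=10)


class TestDirectedLinkClassEnrichment:
    def test_marked_universe_single_class(self):
        universe = _ids("U", 10)
        links = DirectedLinkSet("l", frozenset({(universe[0], universe[1])}))
        res = cinet.directed_link_class_enrichment(
            links, AnnotationSet("m", frozenset(universe)), universe, R=40, seed=0
        )
        assert res.classes["marked->marked"].observed == 1
        assert res.classes["marked->marked"].log2_enrichment == 0.0

    def test_hub_source_marking_enriched(self):
        universe = _ids("U", 12)
        hub = universe[0]
        links = DirectedLinkSet(
            "hub", frozenset((hub, t) for t in universe[1:7])
        )
        res = cinet.directed_link_class_enrichment(
            links, AnnotationSet("m", frozenset({hub})), universe, R=4000, seed=3
        )
        source_in = (
            res.classes["marked->marked"].observed
            + res.classes["marked->unmarked"].observed
        )
        assert source_in == 6
        assert res.classes["marked->unmarked"].log2_enrichment > 0

    def test_no_links_is_not_an_error(self):
        universe = _ids("U", 5)
        res = cinet.directed_link_class_enrichment(
            DirectedLinkSet("none", frozenset()),
            AnnotationSet("m", frozenset(universe[:2])),
            universe,
            R=20,
            seed=0,
        )
        assert all(s.observed == 0 and s.p_value == 1.0 for s in res.classes.values())

    def test_links_outside_universe_dropped(self):
        universe = _ids("U", 6)
        links = DirectedLinkSet(
            "l", frozenset({(universe[0], universe[1]), ("alien", universe[2])})
        )
        res = cinet.directed_link_class_enrichment(
            links, AnnotationSet("m", frozenset(universe[:3])), universe, R=20, seed=0
        )
        assert res.n_edges == 1


class TestGiantComponentTest:
    def test_whole_network_is_trivially_significant(self):
        net = random_string_graph(20, 0.3, seed=6)
        net = cinet.largest_connected_component(net)
        res = cinet.giant_component_test(
            net, AnnotationSet("all", frozenset(net.nodes)), R=30, seed=0
        )
        assert res.observed_lcc == net.number_of_nodes()
        assert res.p_value == 1.0  # every null draw is the whole network too

    def test_planted_triangle_in_sparse_graph(self):
        rng = np.random.default_rng(12)
        nodes = _ids("S", 100)
        net = nx.Graph()
        net.add_nodes_from(nodes)
        for a, b in itertools.combinations(nodes, 2):
            if rng.random() < 0.01:
                net.add_edge(a, b)
        tri = nodes[:3]
        net.add_edges_from([(tri[0], tri[1]), (tri[1], tri[2]), (tri[0], tri[2])])
        res = cinet.giant_component_test(
            net, AnnotationSet("tri", frozenset(tri)), R=2000, seed=9
        )
        assert res.observed_lcc == 3
        assert res.p_value < 0.05

    def test_p_value_floor(self):
        # observed strictly above every null draw → p = 1/(R+1)
        net = nx.path_graph([f"p{i}" for i in range(30)])
        chain = AnnotationSet("chain", frozenset(f"p{i}" for i in range(10)))
        res = cinet.giant_component_test(net, chain, R=200, seed=2)
        assert res.observed_lcc == 10
        if res.null_max < 10:
            assert res.p_value == pytest.approx(1 / 201)
        assert res.p_value >= 1 / 201

    def test_observed_never_exceeds_set_size(self):
        net = random_string_graph(25, 0.2, seed=3)
        node_set = AnnotationSet("s", frozenset(sorted(net.nodes)[:8]))
        res = cinet.giant_component_test(net, node_set, R=100, seed=1)
        assert res.observed_lcc <= res.set_size == 8

    def test_reproducible(self):
        net = random_string_graph(25, 0.2, seed=3)
        node_set = AnnotationSet("s", frozenset(sorted(net.nodes)[:8]))
        a = cinet.giant_component_test(net, node_set, R=100, seed=5)
        b = cinet.giant_component_test(net, node_set, R=100, seed=5)
        assert a == b

    def test_empty_intersection_raises(self):
        net = nx.path_graph(["A", "B"])
        with pytest.raises(ValueError):
            cinet.giant_component_test(net, AnnotationSet("s", frozenset({"Z"})), R=10)
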