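"""Layer aggregation, score shifting, the MWCS heuristic, and the full loop."""

import networkx as nx
import numpy as np
import pytest

from amend.degree_bias import AdjustmentSpec
from amend.graph_model import GraphConfigError, Layer, MultiplexComponent
from amend.module_search import (
    AmendOptions,
    aggregate_multiplex,
    amend_run,
    expand_module,
    mwcs_heuristic,
    score_subnetwork,
    shift_scores,
)
from amend.synthetic import monoplex, plant_module

from conftest import mwcs_exact, random_weighted_graph


def _two_layer_component():
    l1 = Layer.from_edges("phys", [("a", "b", 1.0), ("b", "c", 1.0)])
    l2 = Layer.from_edges("func", [("a", "b", 0.3), ("c", "d", 1.0)])
    return MultiplexComponent("c1", [l1, l2])


class TestAggregateMultiplex:
    def test_single_layer_identity(self):
        comp = MultiplexComponent("c", [Layer.from_edges("l", [("a", "b", 2.0)])])
        agg = aggregate_multiplex(comp, "l", {("l", "a"): 0.1, ("l", "b"): 0.2})
        assert set(agg.graph.nodes) == {"a", "b"}
        assert agg.graph["a"]["b"]["weight"] == 2.0

    def test_mean_score_summary(self):
        comp = _two_layer_component()
        scores = {("phys", "a"): 0.1, ("func", "a"): 0.3, ("phys", "b"): 0.5,
                  ("func", "b"): 0.5, ("phys", "c"): 0.2, ("func", "c"): 0.2,
                  ("func", "d"): 0.4}
        agg = aggregate_multiplex(comp, "phys", scores)
        assert agg.scores["a"] == pytest.approx(0.2)
        assert agg.scores["d"] == pytest.approx(0.4)

    def test_primary_layer_edge_weight_wins(self):
        comp = _two_layer_component()  # (a, b) in both layers, weights 1.0 / 0.3
        scores = {(l.layer_id, v): 0.0 for l in comp.layers for v in l.graph.nodes}
        agg = aggregate_multiplex(comp, "phys", scores)
        assert agg.graph["a"]["b"]["weight"] == 1.0
        assert agg.graph["a"]["b"]["source_layer"] == "phys"
        # pair absent from primary falls back to the secondary layer
        assert agg.graph["c"]["d"]["source_layer"] == "func"

    def test_union_node_set(self):
        comp = _two_layer_component()
        scores = {(l.layer_id, v): 0.0 for l in comp.layers for v in l.graph.nodes}
        agg = aggregate_multiplex(comp, "phys", scores)
        assert set(agg.graph.nodes) == {"a", "b", "c", "d"}

    def test_unknown_primary_layer_rejected(self):
        with pytest.raises(KeyError):
            aggregate_multiplex(_two_layer_component(), "ghost", {})


class TestExpandModule:
    def test_restriction_to_module_nodes(self):
        comp = _two_layer_component()
        subs = expand_module({"a", "b"}, comp)
        assert set(subs["phys"].nodes) == {"a", "b"}
        assert subs["phys"].has_edge("a", "b")
        assert set(subs["func"].nodes) == {"a", "b"}

    def test_full_node_set_is_identity(self):
        comp = _two_layer_component()
        subs = expand_module({"a", "b", "c", "d"}, comp)
        for layer in comp.layers:
            assert set(subs[layer.layer_id].edges) == set(layer.graph.edges)

    def test_nodes_absent_from_layer_simply_absent(self):
        comp = _two_layer_component()
        subs = expand_module({"d"}, comp)
        assert set(subs["phys"].nodes) == set()
        assert set(subs["func"].nodes) == {"d"}


class TestShiftScores:
    def test_half_retention_keeps_ceil_half_nonnegative(self):
        rng = np.random.default_rng(0)
        for n in (5, 8, 13):
            scores = rng.uniform(0.1, 1.0, size=n)
            w, degenerate = shift_scores(scores, 0.5)
            assert not degenerate
            assert (w >= 0).sum() == int(np.ceil(n / 2))

    def test_sign_pattern_invariant_under_scaling(self):
        rng = np.random.default_rng(1)
        scores = rng.uniform(0.1, 1.0, size=20)
        w1, _ = shift_scores(scores, 0.3)
        w2, _ = shift_scores(2.0 * scores, 0.3)
        assert np.array_equal(w1 >= 0, w2 >= 0)

    def test_top_score_gets_max_weight(self):
        scores = np.array([0.5, 2.0, 0.1, 0.9])
        w, _ = shift_scores(scores, 0.5)
        assert np.argmax(w) == 1

    def test_constant_scores_flagged_degenerate(self):
        w, degenerate = shift_scores(np.full(6, 0.4), 0.5)
        assert degenerate
        assert np.all(w == 0.0)

    def test_invalid_retention_rejected(self):
        with pytest.raises(ValueError):
            shift_scores(np.array([1.0, 2.0]), 1.0)


class TestMwcsHeuristic:
    def test_all_positive_connected_returns_everything(self):
        G = nx.path_graph(5)
        w = {v: 1.0 for v in G.nodes}
        assert mwcs_heuristic(G, w) == set(G.nodes)

    def test_single_positive_among_harsh_negatives(self):
        G = nx.star_graph(4)
        w = {0: -10.0, 1: 2.0, 2: -10.0, 3: -10.0, 4: -10.0}
        assert mwcs_heuristic(G, w) == {1}

    def test_cheap_bridge_worth_crossing(self):
        G = nx.path_graph(3)
        out = mwcs_heuristic(G, {0: 2.0, 1: -1.0, 2: 2.0})
        assert out == {0, 1, 2}

    def test_expensive_bridge_not_crossed(self):
        G = nx.path_graph(3)
        out = mwcs_heuristic(G, {0: 2.0, 1: -5.0, 2: 2.0})
        assert out in ({0}, {2})

    def test_no_positive_node_gives_empty_set(self):
        G = nx.path_graph(3)
        assert mwcs_heuristic(G, {v: -1.0 for v in G.nodes}) == set()

    def test_output_is_connected(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            G = random_weighted_graph(int(rng.integers(5, 30)), 0.15, rng)
            w = {v: float(rng.normal()) for v in G.nodes}
            out = mwcs_heuristic(G, w)
            if out:
                assert nx.is_connected(G.subgraph(out))

    def test_within_ninety_percent_of_exhaustive_optimum(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            n = int(rng.integers(4, 11))
            G = random_weighted_graph(n, 0.3, rng)
            w = {v: float(rng.normal(0, 1.5)) for v in G.nodes}
            if all(x < 0 for x in w.values()):
                w[0] = 0.5
            opt, _ = mwcs_exact(G, w)
            heur = sum(w[v] for v in mwcs_heuristic(G, w))
            assert heur >= 0.9 * opt - 1e-9


class TestScoreSubnetwork:
    def _ring_with_values(self):
        G = nx.cycle_graph(10)
        vals = {v: 1.0 if v < 5 else 0.0 for v in G.nodes}
        return G, vals

    def test_connected_beats_fragmented_at_equal_seeds(self):
        G, vals = self._ring_with_values()
        _, _, s_conn = score_subnetwork({0, 1, 2, 3, 4}, vals, G)
        _, _, s_frag = score_subnetwork({0, 2, 4, 6, 8}, {v: 1.0 for v in G.nodes}, G)
        # same mean seed value; the fragmented candidate has no internal edges
        assert s_conn > s_frag

    def test_full_network_experimental_term_is_zero(self):
        G, vals = self._ring_with_values()
        exp_term, _, _ = score_subnetwork(set(G.nodes), vals, G)
        assert exp_term == pytest.approx(0.0, abs=1e-12)

    def test_empty_module_rejected(self):
        G, vals = self._ring_with_values()
        with pytest.raises(ValueError):
            score_subnetwork(set(), vals, G)


class TestAmendRun:
    def test_planted_module_recovered(self):
        G = nx.barabasi_albert_graph(600, 2, seed=5)
        g = monoplex(G)
        truth, seeds = plant_module(g, 15, 3.0, rng=5)
        result = amend_run(
            g,
            seeds,
            AmendOptions(n_target=30, normalization="penalized", k_pen=0.5,
                         adjustment=AdjustmentSpec(method="in")),
        )
        recovered = {n for _, n in result.nodes}
        tp = len(recovered & truth)
        f1 = 2 * tp / (len(recovered) + len(truth))
        assert f1 > 0.5

    def test_subnetwork_sizes_strictly_decrease(self):
        G = nx.barabasi_albert_graph(300, 2, seed=6)
        g = monoplex(G)
        _truth, seeds = plant_module(g, 10, 3.0, rng=6)
        result = amend_run(g, seeds, AmendOptions(n_target=20))
        sizes = [r.n_subnetwork for r in result.records]
        assert all(a > b for a, b in zip(sizes, sizes[1:]))
        assert result.selected_iteration in {r.iteration for r in result.records}

    def test_equal_seeds_complete_without_error(self):
        G = nx.barabasi_albert_graph(150, 2, seed=7)
        g = monoplex(G)
        result = amend_run(g, {"c1": {v: 1.0 for v in G.nodes}}, AmendOptions(n_target=20))
        assert len(result.nodes) > 0

    def test_target_above_network_size_single_iteration(self):
        G = nx.barabasi_albert_graph(40, 2, seed=8)
        g = monoplex(G)
        _truth, seeds = plant_module(g, 5, 3.0, rng=8)
        result = amend_run(g, seeds, AmendOptions(n_target=100, refine_below_target=False))
        assert result.total_iterations == 1
        assert {n for _, n in result.nodes} == set(G.nodes)

    def test_module_connected_on_aggregated_edges(self):
        G = nx.barabasi_albert_graph(300, 2, seed=9)
        g = monoplex(G)
        _truth, seeds = plant_module(g, 12, 3.0, rng=9)
        result = amend_run(g, seeds, AmendOptions(n_target=25))
        module = {n for _, n in result.nodes}
        assert nx.is_connected(G.subgraph(module))

    def test_deterministic_given_inputs(self):
        G = nx.barabasi_albert_graph(200, 2, seed=10)
        g = monoplex(G)
        _truth, seeds = plant_module(g, 10, 3.0, rng=10)
        r1 = amend_run(g, seeds, AmendOptions(n_target=20))
        r2 = amend_run(g, seeds, AmendOptions(n_target=20))
        assert r1.nodes == r2.nodes


class TestAggregationRoundTrip:
    def test_aggregate_mwcs_expand_consistency(self, two_component_graph):
        g = two_component_graph
        # diffuse, aggregate, extract, expand — then check layer provenance
        from amend.diffusion import build_seed_vector, rwr
        from amend.module_search import _aggregated_view
        from amend.transition import assemble_transition

        tm = assemble_transition(g)
        sv = build_seed_vector(g, {"c1": {"a": 1.0, "b": 2.0}, "c2": {"x": 1.0}}, index=tm.index)
        p = rwr(tm, sv).p
        replica_scores = {t: float(p[i]) for i, t in enumerate(tm.index.triples)}
        primary = {"c1": "l1", "c2": "l1"}
        agg_graph, agg_scores = _aggregated_view(g, replica_scores, primary, np.mean)
        w, _ = shift_scores(np.array([agg_scores[v] for v in agg_graph.nodes]), 0.6)
        weights = dict(zip(agg_graph.nodes, w))
        module = mwcs_heuristic(agg_graph, weights)
        assert module
        keep = {}
        for cid, nid in module:
            keep.setdefault(cid, set()).add(nid)
        for comp in g.components:
            subs = expand_module(keep.get(comp.component_id, set()), comp)
            union = set().union(*(set(s.nodes) for s in subs.values()))
            assert union == keep.get(comp.component_id, set())
            for lid, sub in subs.items():
                layer = comp.layer(lid)
                for u, v in sub.edges:
                    assert layer.graph.has_edge(u, v)

    def test_primary_layer_precedence_in_aggregated_edges(self, two_component_graph):
        from amend.module_search import _aggregated_view

        g = two_component_graph
        zeros = {
            (c.component_id, l.layer_id, v): 0.0
            for c in g.components for l in c.layers for v in l.graph.nodes
        }
        agg_graph, _ = _aggregated_view(g, zeros, {"c1": "l1", "c2": "l1"}, np.mean)
        # edge (b, c) exists in both layers of c1 with weights 2.0 / 1.0:
        # the primary layer (l1) wins
        d = agg_graph[("c1", "b")][("c1", "c")]
        assert d["weight"] == 2.0
        assert d["source_layer"] == "l1"
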