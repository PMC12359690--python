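"""Reference-graph assembly, PCSF solving, F1 scoring, grid sweeps."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from ksnet.pcsf_fitting import (
    PCSFParams,
    SignalingGraph,
    assemble_reference,
    f1_of_subnetwork,
    prizes_from_condition,
    solve_pcsf,
    sweep_and_select,
)
from ksnet.types import ProbabilisticNetwork


def kinase_graph(edge_list):
    g = nx.DiGraph()
    for u, v, cost in edge_list:
        g.add_node(u, kind="kinase")
        g.add_node(v, kind="kinase")
        g.add_edge(u, v, cost=cost, probability=1 - cost)
    return SignalingGraph(g)


def random_small_instance(rng, max_nodes=8):
    n = int(rng.integers(3, max_nodes + 1))
    kin = [f"K{i}" for i in range(n)]
    g = nx.DiGraph()
    for k in kin:
        g.add_node(k, kind="kinase")
    m = int(rng.integers(2, min(15, n * (n - 1) // 2) + 1))
    added = set()
    for _ in range(m):
        a, b = rng.choice(n, 2, replace=False)
        if (kin[a], kin[b]) in added or (kin[b], kin[a]) in added:
            continue
        added.add((kin[a], kin[b]))
        g.add_edge(kin[a], kin[b], cost=float(rng.uniform(0, 2)),
                   probability=0.5)
    prizes = {
        k: float(rng.uniform(0, 3)) if rng.random() < 0.7 else 0.0 for k in kin
    }
    params = PCSFParams(int(rng.integers(1, 4)), 1.0,
                        float(rng.choice([0.0, 0.05, 0.5])))
    root_charge = float(rng.uniform(0.3, 1.5))
    return SignalingGraph(g), prizes, params, root_charge


class TestAssembleReference:
    def _nets(self):
        kk = ProbabilisticNetwork.from_records(
            [("K1", "K2", 0.9), ("K2", "K3", 0.5)]
        )
        ks = ProbabilisticNetwork.from_records(
            [("K1", "P1_S1", 0.7), ("K3", "P1_S2", 0.4)]
        )
        return kk, ks

    def test_cost_is_one_minus_probability(self):
        kk, ks = self._nets()
        g = assemble_reference(kk, ks, cutoff=0.5)
        assert g.graph["K1"]["K2"]["cost"] == pytest.approx(0.1)
        assert g.graph["K1"]["P1_S1"]["cost"] == pytest.approx(0.3)

    def test_cutoff_is_strict(self):
        kk, ks = self._nets()
        g = assemble_reference(kk, ks, cutoff=0.5)
        assert ("K2", "K3") not in g.edge_set()  # p = 0.5 excluded
        assert ("K3", "P1_S2") not in g.edge_set()

    def test_sites_are_sink_only(self):
        kk, ks = self._nets()
        g = assemble_reference(kk, ks, cutoff=0.5)
        for n, d in g.graph.nodes(data=True):
            if d["kind"] == "site":
                assert g.graph.out_degree(n) == 0

    def test_empty_graph_raises(self):
        kk, ks = self._nets()
        with pytest.raises(ValueError):
            assemble_reference(kk, ks, cutoff=0.99)

    def test_retained_set_matches_brute_force_filter(self, rng):
        from tests.conftest import random_network_edges

        records = random_network_edges(rng, n_edges=100)
        ks = ProbabilisticNetwork.from_records(records)
        kk = ProbabilisticNetwork.from_records([("K00", "K01", 0.8)])
        g = assemble_reference(kk, ks, cutoff=0.5)
        expected = {(k, s) for k, s, p in records if p > 0.5} | {("K00", "K01")}
        assert g.edge_set() == expected


class TestPrizes:
    def test_absolute_value_and_scaling(self):
        g = kinase_graph([("K1", "K2", 0.5)])
        g.graph.add_node("P1_S1", kind="site")
        g.graph.add_edge("K1", "P1_S1", cost=0.2, probability=0.8)
        cond = pd.Series({"P1_S1": -2.0})
        assert prizes_from_condition(g, cond, 1.0)["P1_S1"] == pytest.approx(2.0)
        assert prizes_from_condition(g, cond, 0.75)["P1_S1"] == pytest.approx(1.5)

    def test_zero_weight_zeroes_prizes(self):
        g = kinase_graph([("K1", "K2", 0.5)])
        g.graph.add_node("P1_S1", kind="site")
        g.graph.add_edge("K1", "P1_S1", cost=0.2, probability=0.8)
        prizes = prizes_from_condition(g, pd.Series({"P1_S1": 3.0}), 0.0)
        assert all(v == 0.0 for v in prizes.values())

    def test_no_overlap_raises(self):
        g = kinase_graph([("K1", "K2", 0.5)])
        with pytest.raises(ValueError, match="no measured site"):
            prizes_from_condition(g, pd.Series({"PX_S9": 1.0}), 1.0)

    def test_matches_brute_force_recompute(self, rng):
        g = kinase_graph([("K1", "K2", 0.5)])
        sites = [f"P1_S{i}" for i in range(1, 51)]
        for s in sites:
            g.graph.add_node(s, kind="site")
            g.graph.add_edge("K1", s, cost=0.2, probability=0.8)
        vals = rng.normal(size=50)
        prizes = prizes_from_condition(g, pd.Series(vals, index=sites), 0.75)
        for s, x in zip(sites, vals):
            assert prizes[s] == pytest.approx(0.75 * abs(x))


class TestSolvePcsf:
    def test_isolated_high_prize_node_forced_in(self):
        g = kinase_graph([("K1", "K2", 10.0)])
        g.graph.add_node("K3", kind="kinase")
        fit = solve_pcsf(g, {"K3": 5.0, "K1": 0.0, "K2": 0.0},
                         PCSFParams(2, 1.0, 0.0), root_charge=1.0)
        assert "K3" in fit.nodes
        assert fit.objective == pytest.approx(1.0)

    def test_expensive_edge_leaves_empty_forest(self):
        """Two prize-1 nodes joined by a cost-3 edge at root charge 1.5:
        enumeration over all four forests gives the empty optimum at 2.0."""
        g = kinase_graph([("K1", "K2", 3.0)])
        fit = solve_pcsf(g, {"K1": 1.0, "K2": 1.0}, PCSFParams(2, 1.0, 0.0),
                         mode="exact_small", root_charge=1.5)
        assert fit.nodes == [] and fit.objective == pytest.approx(2.0)
        heur = solve_pcsf(g, {"K1": 1.0, "K2": 1.0}, PCSFParams(2, 1.0, 0.0),
                          root_charge=1.5)
        assert heur.objective == pytest.approx(2.0)

    def test_heuristic_matches_exact_on_small_suite(self, rng):
        """Heuristic objective equals the exhaustive optimum on 60 random
        instances with <= 8 nodes."""
        for _ in range(60):
            g, prizes, params, rc = random_small_instance(rng)
            exact = solve_pcsf(g, prizes, params, mode="exact_small",
                               root_charge=rc)
            heur = solve_pcsf(g, prizes, params, root_charge=rc)
            assert heur.objective == pytest.approx(exact.objective, abs=1e-9)

    def test_forest_validity(self, rng):
        """Outputs are acyclic, respect the tree cap, and use input edges."""
        for _ in range(40):
            g, prizes, params, rc = random_small_instance(rng)
            fit = solve_pcsf(g, prizes, params, root_charge=rc)
            skeleton = nx.Graph()
            skeleton.add_nodes_from(fit.nodes)
            for u, v in fit.edges:
                assert (u, v) in g.edge_set()
                skeleton.add_edge(u, v)
            if len(skeleton):
                assert nx.is_forest(skeleton)
            if fit.nodes:
                assert nx.number_connected_components(skeleton) == fit.n_trees
                assert fit.n_trees <= params.b

    def test_heuristic_within_trivial_bounds(self, rng):
        """Objective never exceeds the empty-forest or spanning bounds on a
        randomized suite (instances up to 30 nodes)."""
        for _ in range(200):
            n = int(rng.integers(4, 31))
            g = nx.DiGraph()
            kin = [f"K{i}" for i in range(n)]
            for k in kin:
                g.add_node(k, kind="kinase")
            for _ in range(2 * n):
                a, b = rng.choice(n, 2, replace=False)
                if not g.has_edge(kin[a], kin[b]):
                    g.add_edge(kin[a], kin[b], cost=float(rng.uniform(0, 1.5)),
                               probability=0.5)
            sg = SignalingGraph(g)
            prizes = {k: float(rng.uniform(0, 2.5)) for k in kin}
            params = PCSFParams(int(rng.integers(1, 6)), 1.0, 0.005)
            fit = solve_pcsf(sg, prizes, params, root_charge=1.0)
            from ksnet.pcsf_fitting import _Instance, _evaluate

            inst = _Instance(sg, prizes, params, 1.0)
            empty_obj, _, _ = _evaluate(inst, frozenset())
            span_obj, _, _ = _evaluate(inst, frozenset(range(n)))
            assert fit.objective <= empty_obj + 1e-9
            assert fit.objective <= span_obj + 1e-9

    def test_prize_scaling_monotonicity_on_exact_instances(self, rng):
        """Scaling every prize up cannot increase the forfeited-prize term
        valued at the original prizes (exchange argument on exact optima)."""
        for _ in range(20):
            g, prizes, params, rc = random_small_instance(rng, max_nodes=6)
            params = PCSFParams(params.b, params.w, 0.0)  # pure prize scaling
            base = solve_pcsf(g, prizes, params, mode="exact_small",
                              root_charge=rc)
            boosted = {k: 1.5 * v for k, v in prizes.items()}
            up = solve_pcsf(g, boosted, params, mode="exact_small",
                            root_charge=rc)
            total = sum(prizes.values())
            forfeit_base = total - sum(prizes[v] for v in base.nodes)
            forfeit_up = total - sum(prizes[v] for v in up.nodes)
            assert forfeit_up <= forfeit_base + 1e-9

    def test_negative_cost_rejected(self):
        g = nx.DiGraph()
        g.add_node("K1", kind="kinase")
        g.add_node("K2", kind="kinase")
        g.add_edge("K1", "K2", cost=-0.1, probability=1.1)
        with pytest.raises(ValueError, match="negative"):
            SignalingGraph(g)


class TestF1:
    def test_worked_example(self):
        forest = [(f"K{i}", f"P_S{i}") for i in range(20)]
        known = set(forest[:8]) | {("KX", f"P_S{100 + i}") for i in range(2)}
        input_edges = set(forest) | {("KX", f"P_S{100 + i}") for i in range(2)}
        p, r, f1, flags = f1_of_subnetwork(forest, known, input_edges)
        assert p == pytest.approx(8 / 20)
        assert r == pytest.approx(8 / 10)
        assert f1 == pytest.approx(2 * 0.4 * 0.8 / 1.2)

    def test_identity_fit_equals_input_baseline(self):
        edges = [("K1", "P_S1"), ("K2", "P_S2"), ("K3", "P_S3")]
        known = {("K1", "P_S1")}
        p, r, f1, _ = f1_of_subnetwork(edges, known, edges)
        p2, r2, f12, _ = f1_of_subnetwork(edges, known, edges)
        assert (p, r, f1) == (p2, r2, f12)
        assert r == 1.0

    def test_empty_forest_flagged(self):
        p, r, f1, flags = f1_of_subnetwork([], {("K1", "P_S1")},
                                           [("K1", "P_S1")])
        assert p == 0.0 and f1 == 0.0
        assert any("empty_forest" in f for f in flags)

    def test_no_known_overlap_flagged_zero(self):
        p, r, f1, flags = f1_of_subnetwork(
            [("K2", "P_S2")], {("K1", "P_S1")}, [("K1", "P_S1"), ("K2", "P_S2")]
        )
        assert f1 == 0.0 and any("f1_zero" in f for f in flags)


class TestSweep:
    def test_default_grid_cardinality(self):
        assert len(PCSFParams.default_grid()) == 300

    def test_single_grid_point_returned(self):
        g = kinase_graph([("K1", "K2", 0.2)])
        g.graph.add_node("P1_S1", kind="site")
        g.graph.add_edge("K1", "P1_S1", cost=0.1, probability=0.9)
        conds = pd.DataFrame({"c1": pd.Series({"P1_S1": 3.0})})
        best, log = sweep_and_select(
            g, conds, {("K1", "P1_S1")}, grid=[PCSFParams(2, 1.0, 0.0)]
        )
        assert "c1" in best and len(log) == 1
        assert best["c1"].params == PCSFParams(2, 1.0, 0.0)

    def test_condition_without_overlap_flagged_and_skipped(self):
        g = kinase_graph([("K1", "K2", 0.2)])
        conds = pd.DataFrame({"c1": pd.Series({"PX_S9": 1.0})})
        best, log = sweep_and_select(
            g, conds, {("K1", "K2")}, grid=[PCSFParams(1, 1.0, 0.0)]
        )
        assert best == {}
        assert log["flag"].str.contains("unsolvable").all()

    def test_empty_known_edges_rejected(self):
        g = kinase_graph([("K1", "K2", 0.2)])
        with pytest.raises(ValueError):
            sweep_and_select(g, pd.DataFrame(), set())
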