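"""Circuit model: construction, Kirchhoff solve, flow regimes."""

import networkx as nx
import numpy as np
import pytest

from trapchip.ladder import (LadderError, LadderSpec, ResistorNetwork,
                             build_ladder, classify_regime, flows_to_frame,
                             solve_flows, street_entry_fractions,
                             trap_capture_fraction, trap_flow_fractions)

from conftest import brute_force_flows, random_ladder_spec


def edge_counts(net, kind):
    return sum(1 for _ in net.edges(kind))


class TestBuildLadder:
    def test_minimal_cell_edge_counts(self):
        net = build_ladder(LadderSpec(n_traps=1, R_A=1, R_S=1, R_rung=1))
        assert edge_counts(net, "apartment") == 1
        assert edge_counts(net, "serpentine") == 1
        assert edge_counts(net, "rung") == 1
        assert len(net.boundary) == 2

    def test_occupied_trap_conductance_scaled(self):
        net = build_ladder(LadderSpec(n_traps=3, R_A=2.0, kappa=100,
                                      occupied=frozenset({1})))
        apt = {d["trap"]: d["conductance"] for *_, d in net.edges("apartment")}
        assert apt[1] == pytest.approx(1 / 200.0)
        assert apt[0] == apt[2] == pytest.approx(1 / 2.0)

    def test_street_of_47_apartments(self):
        net = build_ladder(LadderSpec(n_traps=47))
        rail_edges = sum(edge_counts(net, k)
                         for k in ("apartment", "serpentine", "rung"))
        assert rail_edges == 3 * 47

    @pytest.mark.parametrize("kwargs", [
        dict(n_traps=0), dict(n_traps=3, R_A=-1.0), dict(n_traps=3, R_S=0.0),
        dict(n_traps=3, R_rung=-0.1), dict(n_traps=2, occupied=frozenset({5})),
        dict(n_traps=2, inlet_pressure=0.0, outlet_pressure=0.0),
    ])
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(LadderError):
            build_ladder(LadderSpec(**kwargs))


class TestSolveFlows:
    def test_single_resistor_ohms_law(self):
        g = nx.MultiGraph()
        R = 4.0
        g.add_edge("inlet", "outlet", conductance=1 / R, kind="apartment", trap=0)
        net = ResistorNetwork(graph=g, boundary={"inlet": 1.0, "outlet": 0.0},
                              trap_nodes=["inlet"], n_traps=1)
        sol = solve_flows(net)
        assert sol.throughflow == pytest.approx(1.0 / R)

    def test_two_trap_ladder_matches_brute_force(self):
        spec = LadderSpec(n_traps=2, R_A=1.3, R_S=4.7, R_rung=0.31,
                          kappa=17.0, occupied=frozenset({0}))
        net = build_ladder(spec)
        sol = solve_flows(net)
        _, expected = brute_force_flows(net)
        for key, flow in expected.items():
            assert sol.edge_flows[key] == pytest.approx(flow, rel=1e-8, abs=1e-12)

    def test_random_ladders_match_brute_force(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            net = build_ladder(random_ladder_spec(rng))
            sol = solve_flows(net)
            _, expected = brute_force_flows(net)
            scale = abs(sol.throughflow)
            for key, flow in expected.items():
                assert sol.edge_flows[key] == pytest.approx(
                    flow, rel=1e-8, abs=1e-8 * scale)

    def test_kirchhoff_conservation_at_interior_nodes(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            net = build_ladder(random_ladder_spec(rng))
            sol = solve_flows(net)
            for node in net.graph.nodes:
                if node in net.boundary:
                    continue
                net_flow = 0.0
                for u, v, k, _ in net.graph.edges(node, keys=True, data=True):
                    key = (u, v, k) if (u, v, k) in sol.edge_flows else (v, u, k)
                    f = sol.edge_flows[key]
                    net_flow += -f if key[0] == node else f
                assert abs(net_flow) <= 1e-9 * abs(sol.throughflow)

    def test_inlet_outflow_equals_outlet_inflow(self):
        net = build_ladder(LadderSpec(n_traps=5, R_A=1, R_S=3))
        sol = solve_flows(net)
        out = 0.0
        for u, v, k, _ in net.graph.edges("outlet", keys=True, data=True):
            key = (u, v, k) if (u, v, k) in sol.edge_flows else (v, u, k)
            f = sol.edge_flows[key]
            out += f if key[0] != "outlet" else -f
        assert out == pytest.approx(sol.throughflow, rel=1e-9)

    def test_disconnected_network_raises(self):
        g = nx.MultiGraph()
        g.add_edge("inlet", "outlet", conductance=1.0, kind="apartment", trap=0)
        g.add_edge("x", "y", conductance=1.0, kind="serpentine", trap=0)
        net = ResistorNetwork(graph=g, boundary={"inlet": 1.0, "outlet": 0.0},
                              trap_nodes=["inlet"], n_traps=1)
        with pytest.raises(LadderError, match="disconnected"):
            solve_flows(net)


class TestRegimes:
    def test_high_efficiency_when_apartment_resistance_lower(self):
        net = build_ladder(LadderSpec(n_traps=6, R_A=1, R_S=10))
        rep = classify_regime(solve_flows(net), net)
        assert rep.regime == "high-efficiency"
        assert all(d == "joining" for d in rep.rung_direction)

    def test_low_efficiency_when_apartment_resistance_higher(self):
        net = build_ladder(LadderSpec(n_traps=6, R_A=10, R_S=1))
        rep = classify_regime(solve_flows(net), net)
        assert rep.regime == "low-efficiency"
        assert all(d == "splitting" for d in rep.rung_direction)

    def test_symmetric_ladder_is_neutral(self):
        net = build_ladder(LadderSpec(n_traps=6, R_A=3.0, R_S=3.0))
        sol = solve_flows(net)
        rep = classify_regime(sol, net)
        assert all(d == "neutral" for d in rep.rung_direction)
        for u, v, k, d in net.edges("rung"):
            assert abs(sol.edge_flows[(u, v, k)]) <= 1e-12 * sol.throughflow

    def test_regime_flips_when_sweeping_apartment_resistance(self):
        for ra, expected in [(0.2, "joining"), (0.999, "joining"),
                             (1.001, "splitting"), (5.0, "splitting")]:
            net = build_ladder(LadderSpec(n_traps=4, R_A=ra, R_S=1.0))
            rep = classify_regime(solve_flows(net), net)
            assert all(d == expected for d in rep.rung_direction), ra


class TestCaptureFraction:
    def test_perfect_trap_in_high_efficiency_regime(self):
        net = build_ladder(LadderSpec(n_traps=8, R_A=1, R_S=10))
        sol = solve_flows(net)
        for i in range(8):
            assert trap_capture_fraction(sol, net, i) == pytest.approx(1.0, abs=1e-9)

    def test_fraction_below_one_in_low_efficiency_regime(self):
        net = build_ladder(LadderSpec(n_traps=8, R_A=10, R_S=1))
        sol = solve_flows(net)
        for i in range(8):
            assert trap_capture_fraction(sol, net, i) < 1.0

    def test_occupied_trap_fraction_below_serpentine_fraction(self):
        spec = LadderSpec(n_traps=5, R_A=1, R_S=10, kappa=100,
                          occupied=frozenset({2}))
        net = build_ladder(spec)
        sol = solve_flows(net)
        apt, ser = trap_flow_fractions(sol, net, 2)
        assert apt < ser

    def test_occupancy_switching_diverts_below_empty_traps(self):
        spec = LadderSpec(n_traps=5, R_A=1, R_S=10, kappa=100,
                          occupied=frozenset({2}))
        net = build_ladder(spec)
        sol = solve_flows(net)
        occupied_frac = trap_capture_fraction(sol, net, 2)
        for i in (0, 1, 3, 4):
            assert occupied_frac < trap_capture_fraction(sol, net, i)

    def test_monotone_in_resistance_ratio(self):
        fractions = []
        for ratio in [0.2, 0.5, 1.0, 2.0, 5.0, 20.0]:
            net = build_ladder(LadderSpec(n_traps=4, R_A=1.0, R_S=ratio))
            sol = solve_flows(net)
            fractions.append(trap_capture_fraction(sol, net, 1))
        assert all(b >= a - 1e-12 for a, b in zip(fractions, fractions[1:]))

    def test_degenerate_single_resistor_fraction_is_one(self):
        g = nx.MultiGraph()
        g.add_edge("inlet", "outlet", conductance=1.0, kind="apartment", trap=0)
        net = ResistorNetwork(graph=g, boundary={"inlet": 1.0, "outlet": 0.0},
                              trap_nodes=["inlet"], n_traps=1)
        sol = solve_flows(net)
        assert trap_capture_fraction(sol, net, 0) == pytest.approx(1.0)

    def test_index_out_of_range(self):
        net = build_ladder(LadderSpec(n_traps=2))
        sol = solve_flows(net)
        with pytest.raises(LadderError):
            trap_capture_fraction(sol, net, 5)

    def test_fast_street_solver_matches_general_path(self):
        rng = np.random.default_rng(23)
        for _ in range(25):
            spec = random_ladder_spec(rng)
            net = build_ladder(spec)
            sol = solve_flows(net)
            general = np.array([trap_capture_fraction(sol, net, i)
                                for i in range(spec.n_traps)])
            fast = street_entry_fractions(spec)
            np.testing.assert_allclose(fast, general, rtol=1e-9, atol=1e-12)


def test_flow_table_export():
    net = build_ladder(LadderSpec(n_traps=3))
    sol = solve_flows(net)
    frame = flows_to_frame(sol, net)
    assert set(frame.columns) == {"kind", "trap", "from", "to", "flow"}
    assert set(frame["kind"]) == {"apartment", "serpentine", "rung", "junction"}
    assert (frame[frame.kind == "apartment"]["flow"] > 0).all()
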