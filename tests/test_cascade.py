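"""CLM cascade dynamics against enumeration oracles and its invariants."""

import numpy as np
import pytest

from hubfail import (
    ConfigurationError,
    attack,
    capacities,
    cascade_step,
    init_efficiency_graph,
    node_loads,
    post_attack_network,
    run_cascade,
)
from hubfail.cascade import CascadeState
from helpers import (
    all_graphs,
    cascade_oracle,
    loads_oracle,
    net_from_edges,
    random_connected_net,
)

# 5-node "square + tail": cycle 0-1-2-3 plus leaf 4 on node 0
SQUARE_TAIL = [(0, 1), (1, 2), (2, 3), (3, 0), (0, 4)]
# detour toy: l1-u, u-a-v, u-b1-b2-v; attacking a forces a longer reroute
DETOUR = [(0, 1), (1, 2), (2, 3), (1, 4), (4, 5), (5, 3)]


class TestInitAndLoads:
    def test_initial_efficiency_is_adjacency(self):
        net = net_from_edges(4, [(0, 1), (2, 3)])
        g = init_efficiency_graph(net)
        np.testing.assert_array_equal(g.efficiency, net.adjacency)
        assert g.initial_efficiency is not g.efficiency

    def test_empty_network_all_zero(self):
        g = init_efficiency_graph(net_from_edges(3, []))
        assert not g.efficiency.any()
        np.testing.assert_array_equal(node_loads(g), np.zeros(3))

    def test_path_graph_loads(self):
        # ordered pairs 0->2 and 2->0 pass through node 1
        g = init_efficiency_graph(net_from_edges(3, [(0, 1), (1, 2)]))
        np.testing.assert_array_equal(node_loads(g), [0, 2, 0])

    def test_star_center_load(self):
        # 4 leaves: 4*3 ordered leaf pairs, each with one path via the center
        g = init_efficiency_graph(net_from_edges(5, [(0, i) for i in range(1, 5)]))
        np.testing.assert_array_equal(node_loads(g), [12, 0, 0, 0, 0])

    def test_complete_graph_zero_loads(self):
        g = init_efficiency_graph(
            net_from_edges(5, [(i, j) for i in range(5) for j in range(i + 1, 5)])
        )
        np.testing.assert_array_equal(node_loads(g), np.zeros(5))

    def test_square_tail_hand_computed(self):
        g = init_efficiency_graph(net_from_edges(5, SQUARE_TAIL))
        np.testing.assert_array_equal(node_loads(g), [10, 4, 2, 4, 0])

    def test_matches_enumeration_on_all_4_node_graphs(self):
        for adj in all_graphs(4):
            g = init_efficiency_graph(net_from_edges(4, []))
            g.efficiency = adj.astype(float)
            np.testing.assert_allclose(node_loads(g), loads_oracle(adj), atol=1e-9)

    def test_matches_enumeration_on_sampled_graphs_up_to_7(self, rng):
        for n in (5, 6, 7):
            for _ in range(40):
                adj = np.triu((rng.random((n, n)) < 0.45).astype(int), 1)
                adj = adj + adj.T
                g = init_efficiency_graph(net_from_edges(n, []))
                g.efficiency = adj.astype(float)
                np.testing.assert_allclose(node_loads(g), loads_oracle(adj), atol=1e-9)

    def test_weighted_links_respected(self):
        # e = 0.5 on a 2-path: distances double but counts are unchanged
        g = init_efficiency_graph(net_from_edges(3, [(0, 1), (1, 2)]))
        g.efficiency = g.efficiency * 0.5
        np.testing.assert_array_equal(node_loads(g), [0, 2, 0])


class TestCapacitiesAndAttack:
    def test_capacity_formula(self):
        np.testing.assert_array_equal(capacities(np.array([0.0, 2, 0]), 1.5), [0, 3, 0])
        np.testing.assert_array_equal(capacities(np.array([1.0, 4]), 1.0), [1, 4])

    def test_capacity_tolerance_below_one_rejected(self):
        with pytest.raises(ConfigurationError):
            capacities(np.ones(3), 0.99)

    def test_star_center_attack_zeroes_everything(self):
        g = attack(init_efficiency_graph(net_from_edges(4, [(0, 1), (0, 2), (0, 3)])), "N00")
        assert not g.efficiency.any()

    def test_leaf_attack_zeroes_only_its_edge(self):
        g0 = init_efficiency_graph(net_from_edges(4, [(0, 1), (0, 2), (0, 3)]))
        g = attack(g0, "N03")
        assert g.efficiency[0, 3] == 0 and g.efficiency[3, 0] == 0
        assert g.efficiency[0, 1] == 1 and g.efficiency[0, 2] == 1

    def test_attack_removes_exactly_hub_degree_pairs(self, rng):
        net = random_connected_net(30, 0.2, rng)
        hub = int(np.argmax(net.degrees()))
        g = attack(init_efficiency_graph(net), net.region_labels[hub])
        removed = (net.adjacency.astype(float) - g.efficiency)
        assert (removed != 0).sum() == 2 * net.degrees()[hub]

    def test_unknown_region_rejected(self):
        g = init_efficiency_graph(net_from_edges(3, [(0, 1)]))
        with pytest.raises(ConfigurationError, match="unknown region"):
            attack(g, "NOPE")


class TestCascadeStep:
    def _state(self, edges, n, target, a):
        net = net_from_edges(n, edges)
        g0 = init_efficiency_graph(net)
        caps = capacities(node_loads(g0), a)
        g = attack(g0, target)
        return CascadeState(t=0, graph=g, loads=node_loads(g), capacities=caps)

    def test_no_overload_restores_non_attacked_edges(self):
        state = self._state(SQUARE_TAIL, 5, "N00", a=10.0)
        nxt = cascade_step(state)
        expected = np.array(state.graph.initial_efficiency)
        expected[0, :] = expected[:, 0] = 0.0
        np.testing.assert_array_equal(nxt.graph.efficiency, expected)
        assert not nxt.overloaded

    def test_double_load_halves_efficiency(self):
        # force L = 2C on node 1 of a path by setting capacities manually
        net = net_from_edges(3, [(0, 1), (1, 2)])
        g = init_efficiency_graph(net)
        loads = node_loads(g)  # (0, 2, 0)
        state = CascadeState(t=0, graph=g, loads=loads,
                             capacities=np.array([0.0, 1.0, 0.0]))
        nxt = cascade_step(state)
        assert nxt.graph.efficiency[0, 1] == pytest.approx(0.5)
        assert nxt.graph.efficiency[1, 2] == pytest.approx(0.5)

    @pytest.mark.parametrize("edges,n,a", [(SQUARE_TAIL, 5, 1.05), (DETOUR, 6, 1.0)])
    def test_trace_matches_enumeration_oracle(self, edges, n, a):
        """Step-for-step match of the first 3 rounds against path enumeration."""
        net = net_from_edges(n, edges)
        g0 = init_efficiency_graph(net)
        hub = int(np.argmax(node_loads(g0)))
        snaps = cascade_oracle(net.adjacency, hub, a, steps=3)
        caps = capacities(node_loads(g0), a)
        g = attack(g0, net.region_labels[hub])
        state = CascadeState(t=0, graph=g, loads=node_loads(g), capacities=caps)
        np.testing.assert_allclose(state.graph.efficiency, snaps[0], atol=1e-12)
        for step in range(1, 4):
            state = cascade_step(state)
            np.testing.assert_allclose(state.graph.efficiency, snaps[step], atol=1e-9)

    def test_detour_attack_degrades_a_non_attacked_edge(self):
        net = net_from_edges(6, DETOUR)
        trace = run_cascade(net, "N02", a=1.0)
        final = trace.final_efficiency
        e0 = np.array(net.adjacency, dtype=float)
        attacked = np.zeros_like(e0, dtype=bool)
        attacked[2, :] = attacked[:, 2] = True
        degraded = (final < e0 - 1e-12) & ~attacked
        assert degraded.any()


class TestRunCascade:
    def test_huge_tolerance_converges_immediately(self):
        net = net_from_edges(5, SQUARE_TAIL)
        trace = run_cascade(net, "N00", a=10.0)
        assert trace.terminated_reason == "converged"
        assert len(trace.states) == 2
        iso = post_attack_network(net, "N00", mode="isolation")
        np.testing.assert_array_equal(trace.final_efficiency, iso.adjacency)

    def test_attacking_isolated_node_is_noop(self):
        net = net_from_edges(4, [(0, 1), (1, 2)])  # node 3 isolated
        trace = run_cascade(net, "N03", a=1.0)
        np.testing.assert_array_equal(trace.final_efficiency, net.adjacency)
        assert trace.terminated_reason == "converged"

    def test_efficiency_never_exceeds_initial(self, rng):
        for _ in range(5):
            net = random_connected_net(12, 0.25, rng)
            hub = net.region_labels[int(np.argmax(net.degrees()))]
            trace = run_cascade(net, hub, a=1.0, max_iter=20)
            e0 = net.adjacency.astype(float)
            for state in trace.states:
                assert (state.graph.efficiency <= e0 + 1e-12).all()
                assert (state.graph.efficiency >= -1e-12).all()

    def test_global_efficiency_never_exceeds_pre_attack(self, rng):
        net = random_connected_net(10, 0.3, rng)
        g0 = init_efficiency_graph(net)
        from hubfail import weighted_global_efficiency

        before = weighted_global_efficiency(g0)
        hub = net.region_labels[int(np.argmax(net.degrees()))]
        trace = run_cascade(net, hub, a=1.0, max_iter=15)
        for state in trace.states:
            assert state.global_efficiency() <= before + 1e-12

    def test_deterministic(self):
        net = net_from_edges(6, DETOUR)
        t1 = run_cascade(net, "N02", a=1.0)
        t2 = run_cascade(net, "N02", a=1.0)
        assert len(t1.states) == len(t2.states)
        for s1, s2 in zip(t1.states, t2.states):
            np.testing.assert_array_equal(s1.graph.efficiency, s2.graph.efficiency)
            np.testing.assert_array_equal(s1.loads, s2.loads)

    def test_infinite_tolerance_limit_equals_isolation(self, rng):
        """For networks where no initially idle node acquires load, a huge
        capacity tolerance reproduces the isolation fault matrix exactly."""
        checked = 0
        for _ in range(10):
            net = random_connected_net(12, 0.3, rng)
            hub = net.region_labels[int(np.argmax(net.degrees()))]
            g0 = init_efficiency_graph(net)
            idle = node_loads(g0) == 0
            post = attack(g0, hub)
            if (node_loads(post)[idle] > 0).any():
                continue  # zero-capacity node gains load: limit genuinely differs
            trace = run_cascade(net, hub, a=1e9)
            iso = post_attack_network(net, hub, mode="isolation")
            np.testing.assert_array_equal(trace.final_efficiency, iso.adjacency)
            checked += 1
        assert checked >= 3


class TestPostAttackNetwork:
    def test_isolation_zeroes_target_degree(self, rng):
        net = random_connected_net(20, 0.25, rng)
        target = net.region_labels[3]
        post = post_attack_network(net, target, mode="isolation")
        assert post.degrees()[3] == 0
        assert post.n_edges == net.n_edges - net.degrees()[3]

    def test_isolation_leaves_non_incident_entries_bitwise_identical(self):
        net = net_from_edges(6, [(0, 1), (0, 2), (0, 3), (1, 2), (3, 4), (4, 5)])
        post = post_attack_network(net, "N00", mode="isolation")
        assert net.degrees()[0] == 3 and post.n_edges == net.n_edges - 3
        keep = np.ones(6, dtype=bool)
        keep[0] = False
        np.testing.assert_array_equal(
            post.adjacency[np.ix_(keep, keep)], net.adjacency[np.ix_(keep, keep)]
        )

    def test_cascade_final_mode_removes_fully_failed_edges(self):
        net = net_from_edges(6, DETOUR)
        post = post_attack_network(net, "N02", mode="cascade_final", a=1.0)
        iso = post_attack_network(net, "N02", mode="isolation")
        assert (post.adjacency <= iso.adjacency).all()

    def test_unknown_mode_rejected(self):
        net = net_from_edges(3, [(0, 1)])
        with pytest.raises(ConfigurationError):
            post_attack_network(net, "N00", mode="bogus")
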