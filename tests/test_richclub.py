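"""Rich-club coefficients, degree-preserving nulls, and the connection
decomposition with its conservation law."""

import numpy as np
import pytest

from hubfail import (
    MeanNetwork,
    RichNodeSet,
    decompose_connections,
    phi,
    phi_norm_curve,
    post_attack_network,
    randomize_network,
    select_rich_nodes,
)
from helpers import net_from_edges, phi_oracle, random_connected_net


def _complete(n, labels=None):
    return net_from_edges(n, [(i, j) for i in range(n) for j in range(i + 1, n)],
                          labels=labels)


class TestPhi:
    def test_clique_is_one_for_low_k(self):
        net = _complete(5)
        for k in (1, 2, 3):
            assert phi(net, k) == 1.0

    def test_cycle_with_chord_values(self):
        # degrees (3, 2, 3, 2): k=2 survivors {0, 2} joined by the chord
        net = net_from_edges(4, [(0, 1), (1, 2), (2, 3), (3, 0), (0, 2)])
        assert phi(net, 2) == 1.0
        assert phi(net, 1) == pytest.approx(5 / 6)

    def test_star_undefined_above_leaf_degree(self):
        net = net_from_edges(5, [(0, i) for i in range(1, 5)])
        assert phi(net, 1) is None  # only the center survives

    def test_matches_subgraph_oracle_on_small_graphs(self, rng):
        for n in (4, 5, 6, 7):
            for _ in range(40):
                adj = np.triu((rng.random((n, n)) < 0.45).astype(int), 1)
                adj = adj + adj.T
                net = net_from_edges(n, np.argwhere(np.triu(adj, 1)))
                for k in range(1, n):
                    expected = phi_oracle(adj, k)
                    got = phi(net, k)
                    if expected is None:
                        assert got is None
                    else:
                        assert got == pytest.approx(expected, abs=1e-12)


class TestRandomize:
    def test_degree_sequence_preserved(self, rng):
        net = random_connected_net(20, 0.25, rng)
        rand = randomize_network(net, seed=5)
        np.testing.assert_array_equal(np.sort(rand.degrees()), np.sort(net.degrees()))
        np.testing.assert_array_equal(rand.degrees(), net.degrees())

    def test_triangle_is_its_own_randomization(self):
        net = net_from_edges(3, [(0, 1), (1, 2), (0, 2)])
        rand = randomize_network(net, seed=1)
        np.testing.assert_array_equal(rand.adjacency, net.adjacency)

    def test_rewiring_actually_changes_edges(self, rng):
        net = random_connected_net(20, 0.2, rng)
        changed = any(
            (randomize_network(net, seed=s, swaps_per_edge=10).adjacency
             != net.adjacency).any()
            for s in range(3)
        )
        assert changed

    def test_deterministic_given_seed(self, rng):
        net = random_connected_net(15, 0.3, rng)
        a = randomize_network(net, seed=42).adjacency
        b = randomize_network(net, seed=42).adjacency
        np.testing.assert_array_equal(a, b)

    def test_stays_simple(self, rng):
        net = random_connected_net(12, 0.4, rng)
        rand = randomize_network(net, seed=9)
        assert not np.diag(rand.adjacency).any()
        assert np.isin(rand.adjacency, (0, 1)).all()


class TestPhiNormCurve:
    def test_k_range_and_undefined_tail(self, rng):
        net = random_connected_net(12, 0.3, rng)
        curve = phi_norm_curve(net, n_random=5, base_seed=0)
        np.testing.assert_array_equal(curve.k_values, np.arange(1, 12))
        max_deg = net.degrees().max()
        assert np.isnan(curve.phi[curve.k_values >= max_deg]).all()

    def test_complete_graph_normalizes_to_one(self):
        net = _complete(6)
        curve = phi_norm_curve(net, n_random=4, base_seed=0)
        defined = ~np.isnan(curve.phi_norm)
        np.testing.assert_allclose(curve.phi_norm[defined], 1.0)

    def test_planted_clique_exceeds_one(self, rng):
        """A dense 9-clique over sparse background is rich-club organised."""
        n = 40
        adj = np.triu((rng.random((n, n)) < 0.08).astype(int), 1)
        adj = adj + adj.T
        adj[np.ix_(range(9), range(9))] = 1
        np.fill_diagonal(adj, 0)
        net = net_from_edges(n, np.argwhere(np.triu(adj, 1)))
        curve = phi_norm_curve(net, n_random=20, base_seed=3)
        defined = ~np.isnan(curve.phi_norm)
        assert (curve.phi_norm[defined & (curve.k_values >= 5)
                               & (curve.k_values <= 8)] > 1.0).any()

    def test_deterministic_given_base_seed(self, rng):
        net = random_connected_net(15, 0.3, rng)
        c1 = phi_norm_curve(net, n_random=6, base_seed=17)
        c2 = phi_norm_curve(net, n_random=6, base_seed=17)
        np.testing.assert_array_equal(
            np.nan_to_num(c1.phi_norm), np.nan_to_num(c2.phi_norm)
        )


class TestRichSelection:
    def test_ninety_nodes_give_nine_rich(self, rng):
        net = random_connected_net(90, 0.15, rng)
        mean = MeanNetwork(net.adjacency.astype(float), net.region_labels, 1)
        rich = select_rich_nodes(mean, 0.10)
        assert len(rich.rich) == 9

    def test_all_equal_strengths_tie_break(self):
        labels = [f"R{i}" for i in range(10)]
        mean = MeanNetwork(_complete(10).adjacency.astype(float), labels, 1)
        rich = select_rich_nodes(mean, 0.3)
        assert list(rich.rich) == labels[:3]

    def test_descending_strengths(self):
        n = 10
        w = np.zeros((n, n))
        # node i connected to nodes i+1.. with weight 1: strengths descend
        for i in range(n):
            for j in range(i + 1, n):
                w[i, j] = w[j, i] = (n - i) / n
        mean = MeanNetwork(w / w.max(), [f"R{i}" for i in range(n)], 1)
        rich = select_rich_nodes(mean, 0.2)
        assert list(rich.rich) == ["R0", "R1"]


class TestDecomposition:
    def test_empty_and_full_rich_sets(self, rng):
        net = random_connected_net(10, 0.3, rng)
        empty = decompose_connections(net, RichNodeSet(rich=()))
        assert empty.rich_sum == 0 and empty.feeder_sum == 0
        assert empty.local_sum == net.n_edges
        full = decompose_connections(net, RichNodeSet(rich=net.region_labels))
        assert full.rich_sum == net.n_edges
        assert full.feeder_sum == 0 and full.local_sum == 0

    def test_five_node_example(self):
        # rich={0,1}, edges {01, 02, 13, 23, 34} -> rich=1, feeder=2, local=2
        net = net_from_edges(5, [(0, 1), (0, 2), (1, 3), (2, 3), (3, 4)])
        dec = decompose_connections(net, RichNodeSet(rich=("N00", "N01")))
        assert (dec.rich_sum, dec.feeder_sum, dec.local_sum) == (1, 2, 2)

    def test_unknown_rich_label_rejected(self):
        net = net_from_edges(3, [(0, 1)])
        with pytest.raises(Exception, match="rich labels"):
            decompose_connections(net, RichNodeSet(rich=("NOPE",)))

    def test_conservation_on_100_seeded_networks(self):
        """rich + feeder + local equals total edge weight, exactly."""
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(8, 25))
            net = random_connected_net(n, 0.3, rng)
            n_rich = int(rng.integers(0, n + 1))
            rich = RichNodeSet(rich=tuple(
                net.region_labels[i]
                for i in rng.choice(n, size=n_rich, replace=False)
            ))
            dec = decompose_connections(net, rich)
            assert dec.total == net.n_edges  # integers: exact

    def test_rich_node_attack_moves_weight_predictably(self, rng):
        net = random_connected_net(15, 0.3, rng)
        mean = MeanNetwork(net.adjacency.astype(float), net.region_labels, 1)
        rich = select_rich_nodes(mean, 0.2)
        target = rich.rich[0]
        idx = net.region_labels.index(target)
        is_rich = np.array([lab in rich.rich for lab in net.region_labels])
        to_rich = int(net.adjacency[idx][is_rich].sum())
        to_nonrich = int(net.adjacency[idx][~is_rich].sum())
        pre = decompose_connections(net, rich)
        post = decompose_connections(post_attack_network(net, target), rich)
        assert pre.rich_sum - post.rich_sum == to_rich
        assert pre.feeder_sum - post.feeder_sum == to_nonrich
        assert pre.local_sum == post.local_sum
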