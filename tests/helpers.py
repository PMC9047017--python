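"""Shared builders and independent brute-force oracles for the test suite.

Every oracle here deliberately takes a different computational route from
the implementation it checks: dense eigendecomposition instead of power
iteration, explicit path enumeration instead of count propagation, explicit
subgraph construction instead of suffix counting, Floyd-Warshall instead of
breadth-first search.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np

from hubfail import BinaryNetwork


def net_from_edges(n: int, edges, labels=None) -> BinaryNetwork:
    adj = np.zeros((n, n), dtype=int)
    for i, j in edges:
        adj[i, j] = adj[j, i] = 1
    labels = labels if labels is not None else [f"N{i:02d}" for i in range(n)]
    return BinaryNetwork(adj, labels)


def random_connected_net(n: int, p: float, rng: np.random.Generator) -> BinaryNetwork:
    """Seeded G(n, p) conditioned on connectivity (resampled until connected)."""
    while True:
        adj = (rng.random((n, n)) < p).astype(int)
        adj = np.triu(adj, 1)
        adj = adj + adj.T
        if adj.any() and nx.is_connected(nx.from_numpy_array(adj)):
            return BinaryNetwork(adj, [f"N{i:02d}" for i in range(n)])


def all_graphs(n: int):
    """Every labelled simple graph on n nodes, as adjacency matrices."""
    pairs = list(itertools.combinations(range(n), 2))
    for bits in itertools.product((0, 1), repeat=len(pairs)):
        adj = np.zeros((n, n), dtype=int)
        for (i, j), b in zip(pairs, bits):
            adj[i, j] = adj[j, i] = b
        yield adj


# -- oracles ----------------------------------------------------------------

def perron_oracle(adj: np.ndarray) -> tuple[np.ndarray, float]:
    """Principal eigenvector/value by dense symmetric eigendecomposition."""
    w, v = np.linalg.eigh(np.asarray(adj, dtype=float))
    x = v[:, -1]
    # sign-align to the nonnegative orientation
    if x[np.argmax(np.abs(x))] < 0:
        x = -x
    return x, float(w[-1])


def clustering_oracle(adj: np.ndarray) -> np.ndarray:
    """c_i by explicit triangle counting over neighbour pairs."""
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(adj[i])
        k = nbrs.size
        if k < 2:
            continue
        e = sum(adj[u, v] for u, v in itertools.combinations(nbrs, 2))
        out[i] = 2.0 * e / (k * (k - 1))
    return out


def global_efficiency_oracle(adj: np.ndarray) -> float:
    """Mean inverse distance via Floyd-Warshall."""
    n = adj.shape[0]
    d = np.where(adj > 0, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        d = np.minimum(d, d[:, k][:, None] + d[k, :][None, :])
    off = ~np.eye(n, dtype=bool)
    inv = np.where(np.isfinite(d) & (d > 0), 1.0 / np.where(d > 0, d, 1.0), 0.0)
    return float(inv[off].sum() / (n * (n - 1))) if n > 1 else 0.0


def phi_oracle(adj: np.ndarray, k: int) -> float | None:
    """Rich-club coefficient by explicit subgraph construction."""
    deg = adj.sum(axis=1)
    surv = np.flatnonzero(deg > k)
    if surv.size < 2:
        return None
    sub = adj[np.ix_(surv, surv)]
    e = sub.sum() / 2
    return 2.0 * e / (surv.size * (surv.size - 1))


def loads_oracle(eff: np.ndarray) -> np.ndarray:
    """Ordered-pair shortest-path counts through each node, by enumerating
    every shortest path (networkx Dijkstra on lengths 1/e)."""
    n = eff.shape[0]
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if eff[i, j] > 0:
                g.add_edge(i, j, weight=1.0 / eff[i, j])
    loads = np.zeros(n)
    for s in range(n):
        for u in range(n):
            if s == u:
                continue
            try:
                paths = nx.all_shortest_paths(g, s, u, weight="weight")
                for path in paths:
                    for node in path[1:-1]:
                        loads[node] += 1
            except nx.NetworkXNoPath:
                continue
    return loads


def cascade_oracle(adj: np.ndarray, target: int, a: float, steps: int):
    """Efficiency matrices of the first ``steps`` failure rounds, with loads
    computed by full path enumeration (independent of the implementation's
    count propagation)."""
    e0 = np.asarray(adj, dtype=float)
    caps = a * loads_oracle(e0)
    removed = np.zeros_like(e0, dtype=bool)
    removed[target, :] = removed[:, target] = True
    e = e0.copy()
    e[removed] = 0.0
    snaps = [e.copy()]
    for _ in range(steps):
        loads = loads_oracle(e)
        factor = np.ones_like(loads)
        over = loads > caps
        factor[over] = np.where(loads[over] > 0, caps[over] / loads[over], 0.0)
        e = e0 * np.minimum(factor[:, None], factor[None, :])
        e[removed] = 0.0
        snaps.append(e.copy())
    return snaps
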