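"""Load-capacity (CLM) sequential-failure simulation of a targeted hub attack.

The model treats the binary network as a transport system.  Each edge carries
a transmission efficiency e_ij, initialised to 1 for existing edges (unit
link length, so adjacent shortest distance is 1) and 0 otherwise.  The load
L_i(t) of a node is the number of shortest paths between ordered pairs of
other nodes that pass through it as an intermediate, with link lengths
d_ij = 1 / e_ij and all co-optimal paths counted.  Capacities are fixed at
C_i = a * L_i(0) (a >= 1) from the intact network.  The attack does not
delete the hub: it permanently zeroes the efficiencies of its incident
edges.  Load then redistributes; any node with L_i(t) > C_i degrades its
incident edges to e_ij(0) * C_i / L_i(t), while edges of non-overloaded
nodes recover to their initial efficiency (attacked edges never recover).
When both endpoints of an edge are overloaded the smaller prescribed value
wins.  The process iterates until the overloaded set is empty and the
efficiency matrix is stationary, or a maximum number of rounds is reached.

Downstream group comparisons use the *isolation* fault matrix — hub row and
column zeroed, everything else untouched — exactly the a -> infinity limit
of the cascade on networks where no initially idle node acquires load.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import dijkstra

from .errors import ConfigurationError
from .netbuild import BinaryNetwork

#: relative tolerance for declaring two path lengths co-optimal
PATH_RTOL = 1e-9
#: max-norm efficiency change below which the cascade is stationary
CONVERGENCE_EPS = 1e-12
DEFAULT_CAPACITY_TOLERANCE = 1.2
DEFAULT_MAX_ITER = 100


@dataclass
class EfficiencyGraph:
    """Evolving edge-efficiency matrix plus the frozen t=0 state."""

    efficiency: np.ndarray
    initial_efficiency: np.ndarray
    removed: np.ndarray  # bool mask of permanently attacked entries
    region_labels: tuple[str, ...]

    def copy(self) -> "EfficiencyGraph":
        return EfficiencyGraph(
            self.efficiency.copy(),
            self.initial_efficiency,
            self.removed,
            self.region_labels,
        )

    @property
    def n_nodes(self) -> int:
        return self.efficiency.shape[0]


@dataclass
class CascadeState:
    """One cascade round: current graph, its loads, and the fixed capacities."""

    t: int
    graph: EfficiencyGraph
    loads: np.ndarray
    capacities: np.ndarray

    @property
    def efficiency(self) -> np.ndarray:
        return self.graph.efficiency

    @property
    def overloaded(self) -> tuple[int, ...]:
        return tuple(np.flatnonzero(self.loads > self.capacities))

    def global_efficiency(self) -> float:
        return weighted_global_efficiency(self.graph)


@dataclass
class CascadeTrace:
    """Ordered cascade states plus why the run stopped."""

    states: list[CascadeState] = field(default_factory=list)
    terminated_reason: str = "max_iter"  # "converged" | "max_iter"
    target: str | None = None
    capacity_tolerance: float | None = None

    @property
    def final_efficiency(self) -> np.ndarray:
        return self.states[-1].graph.efficiency


def init_efficiency_graph(net: BinaryNetwork) -> EfficiencyGraph:
    """e_ij(0) = 1 on edges, 0 elsewhere; the t=0 matrix is frozen."""
    e0 = net.adjacency.astype(float)
    return EfficiencyGraph(
        efficiency=e0.copy(),
        initial_efficiency=e0,
        removed=np.zeros_like(e0, dtype=bool),
        region_labels=net.region_labels,
    )


def _distances_and_counts(eff: np.ndarray, rtol: float = PATH_RTOL):
    """All-pairs shortest distances and co-optimal path counts.

    Link length is 1/e (e = 0 means no link).  Counts sigma[s, v] are the
    number of distinct shortest s->v paths; ties in length are declared at
    relative tolerance ``rtol``.
    """
    n = eff.shape[0]
    with np.errstate(divide="ignore"):
        lengths = np.where(eff > 0, 1.0 / np.where(eff > 0, eff, 1.0), np.inf)
    np.fill_diagonal(lengths, np.inf)
    finite = np.isfinite(lengths)
    if not finite.any():
        d = np.full((n, n), np.inf)
        np.fill_diagonal(d, 0.0)
        return d, np.eye(n)
    rows, cols = np.nonzero(finite)
    graph = sp.csr_matrix((lengths[rows, cols], (rows, cols)), shape=(n, n))
    d = dijkstra(graph, directed=True)
    sigma = np.zeros((n, n))
    for s in range(n):
        ds = d[s]
        sig = np.zeros(n)
        sig[s] = 1.0
        for v in np.argsort(ds, kind="stable"):
            if v == s or not np.isfinite(ds[v]):
                continue
            w_to_v = lengths[:, v]
            with np.errstate(invalid="ignore"):
                pred = (
                    np.isfinite(w_to_v)
                    & np.isfinite(ds)
                    & (np.abs(ds + w_to_v - ds[v]) <= rtol * max(ds[v], 1.0))
                )
            sig[v] = sig[pred].sum()
        sigma[s] = sig
    return d, sigma


def node_loads(g: EfficiencyGraph) -> np.ndarray:
    """Number of ordered-pair shortest paths passing through each node.

    L_i = #{shortest s->u paths with i as an intermediate node}, counting
    every co-optimal path, over all ordered pairs s != u, both distinct
    from i.  Disconnected pairs contribute nothing.
    """
    d, sigma = _distances_and_counts(g.efficiency)
    n = g.n_nodes
    loads = np.zeros(n)
    for i in range(n):
        via = d[:, i][:, None] + d[i, :][None, :]
        with np.errstate(invalid="ignore"):
            on_path = np.abs(via - d) <= PATH_RTOL * np.maximum(d, 1.0)
        on_path &= np.isfinite(d)
        on_path[i, :] = False
        on_path[:, i] = False
        np.fill_diagonal(on_path, False)
        contrib = sigma[:, i][:, None] * sigma[i, :][None, :]
        loads[i] = contrib[on_path].sum()
    return loads


def capacities(initial_loads: np.ndarray, a: float) -> np.ndarray:
    """C_i = a * L_i(0), the fixed per-node capacity (a >= 1)."""
    if a < 1:
        raise ConfigurationError(f"capacity tolerance a must be >= 1, got {a}")
    return a * np.asarray(initial_loads, dtype=float)


def weighted_global_efficiency(g: EfficiencyGraph) -> float:
    """Mean inverse shortest distance over ordered pairs of the current graph."""
    d, _ = _distances_and_counts(g.efficiency)
    n = g.n_nodes
    if n < 2:
        return 0.0
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / np.where(d > 0, d, 1.0), 0.0)
    return float(inv[off].sum() / (n * (n - 1)))


def _target_index(labels: tuple[str, ...], target: str) -> int:
    try:
        return labels.index(target)
    except ValueError:
        raise ConfigurationError(f"unknown region {target!r}") from None


def attack(g: EfficiencyGraph, target: str) -> EfficiencyGraph:
    """Zero all efficiencies incident to the target, permanently."""
    idx = _target_index(g.region_labels, target)
    out = g.copy()
    removed = out.removed.copy()
    removed[idx, :] = True
    removed[:, idx] = True
    out.removed = removed
    out.efficiency[idx, :] = 0.0
    out.efficiency[:, idx] = 0.0
    return out


def _next_efficiency(g: EfficiencyGraph, loads: np.ndarray, caps: np.ndarray) -> np.ndarray:
    over = loads > caps
    factor = np.ones_like(loads)
    with np.errstate(divide="ignore", invalid="ignore"):
        factor[over] = np.where(loads[over] > 0, caps[over] / loads[over], 0.0)
    # edge gets the more degraded of its two endpoint prescriptions
    pair = np.minimum(factor[:, None], factor[None, :])
    e_next = g.initial_efficiency * pair
    e_next[g.removed] = 0.0
    return e_next


def cascade_step(state: CascadeState) -> CascadeState:
    """One load-redistribution round: degrade/restore edges, recompute loads."""
    e_next = _next_efficiency(state.graph, state.loads, state.capacities)
    g = state.graph.copy()
    g.efficiency = e_next
    return CascadeState(
        t=state.t + 1,
        graph=g,
        loads=node_loads(g),
        capacities=state.capacities,
    )


def run_cascade(
    net: BinaryNetwork,
    target: str,
    a: float = DEFAULT_CAPACITY_TOLERANCE,
    max_iter: int = DEFAULT_MAX_ITER,
) -> CascadeTrace:
    """Attack the target and iterate the failure dynamics to stationarity.

    Capacities come from the intact network's loads.  The trace records one
    state per round, starting with the state right after the attack, and
    stops when no node is overloaded and the efficiency matrix is stationary
    (or after ``max_iter`` rounds).
    """
    g0 = init_efficiency_graph(net)
    caps = capacities(node_loads(g0), a)
    g = attack(g0, target)
    state = CascadeState(t=0, graph=g, loads=node_loads(g), capacities=caps)
    trace = CascadeTrace(target=target, capacity_tolerance=a)
    trace.states.append(state)
    for _ in range(max_iter):
        new_state = cascade_step(state)
        trace.states.append(new_state)
        e_change = np.max(np.abs(new_state.graph.efficiency - state.graph.efficiency))
        no_overload = not new_state.overloaded
        state = new_state
        if no_overload and e_change < CONVERGENCE_EPS:
            trace.terminated_reason = "converged"
            break
    else:
        trace.terminated_reason = "max_iter"
    return trace


def post_attack_network(
    net: BinaryNetwork, target: str, mode: str = "isolation", **cascade_kwargs
) -> BinaryNetwork:
    """Fault matrix after the attack.

    ``isolation`` (default): the target's row and column are zeroed and every
    other entry is untouched.  ``cascade_final``: additionally removes edges
    whose efficiency ended at 0 after running the full cascade.
    """
    idx = _target_index(net.region_labels, target)
    adj = net.adjacency.copy()
    adj[idx, :] = 0
    adj[:, idx] = 0
    if mode == "isolation":
        return BinaryNetwork(adj, net.region_labels, threshold_used=net.threshold_used)
    if mode == "cascade_final":
        trace = run_cascade(net, target, **cascade_kwargs)
        adj = adj * (trace.final_efficiency > 0)
        return BinaryNetwork(adj, net.region_labels, threshold_used=net.threshold_used)
    raise ConfigurationError(f"unknown attack mode {mode!r}")
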