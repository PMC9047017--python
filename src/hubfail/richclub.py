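"""Rich-club organisation: phi(k) curves, degree-preserving nulls, and the
rich / feeder / local connection decomposition.

phi(k) restricts the network to nodes whose full-network degree is strictly
greater than k and measures the edge density of that subgraph,
phi(k) = 2 E_{>k} / (N_{>k} (N_{>k} - 1)); it is undefined when fewer than
two nodes survive.  Because high-degree nodes interconnect more often than
chance even in random graphs, phi is normalised by the mean coefficient of
an ensemble of degree-preserving (double-edge-swap) rewirings:
phi_norm(k) = phi(k) / mean phi_random(k).  Values above 1 over a range of k
indicate rich-club organisation.

Rich nodes are the top 10% of regions by strength (weighted degree) of the
healthy-control group-mean network; the same set is applied to both groups.
Edges then partition into rich-rich, rich-nonrich (feeder) and
nonrich-nonrich (local) connections, whose weight sums are conserved:
rich + feeder + local = total edge weight, exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .errors import ConfigurationError
from .netbuild import BinaryNetwork, MeanNetwork

DEFAULT_N_RANDOM = 100
DEFAULT_SWAPS_PER_EDGE = 10
RICH_FRACTION = 0.10


@dataclass(frozen=True)
class RichClubCurve:
    """phi, null-mean phi and their ratio, indexed by degree threshold k.

    Undefined entries are NaN: phi is undefined where fewer than two nodes
    survive the threshold, phi_norm additionally wherever the null mean is
    undefined or zero.
    """

    k_values: np.ndarray
    phi: np.ndarray
    phi_random_mean: np.ndarray
    phi_norm: np.ndarray
    n_random: int


@dataclass(frozen=True)
class RichNodeSet:
    """Ordered rich-node labels plus where they came from."""

    rich: tuple[str, ...]
    source: str = ""

    def __contains__(self, label: str) -> bool:
        return label in self.rich


@dataclass(frozen=True)
class ConnectionDecomposition:
    """Edge-weight sums by endpoint class; conserves total weight exactly."""

    rich_sum: float
    feeder_sum: float
    local_sum: float

    @property
    def total(self) -> float:
        return self.rich_sum + self.feeder_sum + self.local_sum


def phi(net: BinaryNetwork, k: int) -> float | None:
    """Rich-club coefficient at degree threshold k; None when undefined."""
    if k < 1:
        raise ConfigurationError(f"degree threshold k must be >= 1, got {k}")
    deg = net.degrees()
    surv = deg > k
    n_surv = int(surv.sum())
    if n_surv < 2:
        return None
    e_surv = int(net.adjacency[np.ix_(surv, surv)].sum()) // 2
    return 2.0 * e_surv / (n_surv * (n_surv - 1))


def _phi_curve(adjacency: np.ndarray, k_values: np.ndarray) -> np.ndarray:
    """phi over all k at once via min-endpoint-degree suffix counts."""
    deg = adjacency.sum(axis=1)
    iu = np.triu_indices(adjacency.shape[0], 1)
    edge_min = np.minimum(deg[iu[0]], deg[iu[1]])[adjacency[iu] > 0]
    out = np.full(k_values.shape, np.nan)
    for idx, k in enumerate(k_values):
        n_surv = int((deg > k).sum())
        if n_surv < 2:
            continue
        e_surv = int((edge_min > k).sum())
        out[idx] = 2.0 * e_surv / (n_surv * (n_surv - 1))
    return out


def randomize_network(
    net: BinaryNetwork,
    seed: int,
    swaps_per_edge: int = DEFAULT_SWAPS_PER_EDGE,
) -> BinaryNetwork:
    """Degree-preserving double-edge-swap rewiring (Maslov-Sneppen style).

    Every node keeps its exact degree and the graph stays simple; swap
    attempts that would create a self-loop or multi-edge are skipped.
    Deterministic given ``seed``.  Networks too small to admit any swap are
    returned unchanged.
    """
    if net.n_edges < 2:
        raise ConfigurationError("rewiring needs at least 2 edges")
    g = nx.from_numpy_array(net.adjacency)
    nswap = swaps_per_edge * net.n_edges
    if g.number_of_nodes() >= 4:
        try:
            nx.double_edge_swap(g, nswap=nswap, max_tries=100 * nswap, seed=seed)
        except nx.NetworkXAlgorithmError:
            pass  # attempt budget exhausted: keep the swaps made so far
        except nx.NetworkXError:
            pass  # e.g. rigid degree sequence with no admissible swap
    adj = nx.to_numpy_array(g, nodelist=range(net.n_nodes), dtype=np.int8)
    return BinaryNetwork(adj, net.region_labels, threshold_used=net.threshold_used)


def phi_norm_curve(
    net: BinaryNetwork,
    n_random: int = DEFAULT_N_RANDOM,
    base_seed: int = 0,
    swaps_per_edge: int = DEFAULT_SWAPS_PER_EDGE,
) -> RichClubCurve:
    """phi(k) for k = 1..N-1 normalised by a degree-preserving null ensemble.

    The null mean at each k averages only ensemble members where phi is
    defined there (the degree sequence is shared, so in practice all of
    them).  Per-replicate seeds are base_seed + replicate index.
    """
    n = net.n_nodes
    k_values = np.arange(1, n)
    phi_net = _phi_curve(net.adjacency, k_values)
    null_sum = np.zeros(k_values.shape)
    null_count = np.zeros(k_values.shape, dtype=int)
    for rep in range(n_random):
        rand = randomize_network(net, seed=base_seed + rep, swaps_per_edge=swaps_per_edge)
        phi_r = _phi_curve(rand.adjacency, k_values)
        ok = ~np.isnan(phi_r)
        null_sum[ok] += phi_r[ok]
        null_count[ok] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        phi_rand = np.where(null_count > 0, null_sum / np.maximum(null_count, 1), np.nan)
        phi_norm = np.where(
            (~np.isnan(phi_net)) & (~np.isnan(phi_rand)) & (phi_rand > 0),
            phi_net / phi_rand,
            np.nan,
        )
    return RichClubCurve(
        k_values=k_values,
        phi=phi_net,
        phi_random_mean=phi_rand,
        phi_norm=phi_norm,
        n_random=n_random,
    )


def select_rich_nodes(mean_net: MeanNetwork, fraction: float = RICH_FRACTION) -> RichNodeSet:
    """Top ceil(fraction * N) regions by strength; ties broken by label order."""
    if not 0 < fraction <= 1:
        raise ConfigurationError(f"fraction must be in (0, 1], got {fraction}")
    strength = mean_net.strengths()
    n_rich = math.ceil(fraction * mean_net.n_nodes)
    order = np.argsort(-strength, kind="stable")[:n_rich]
    return RichNodeSet(
        rich=tuple(mean_net.region_labels[i] for i in order),
        source=f"strength top {fraction:g} of mean network (n={mean_net.n_subjects})",
    )


def decompose_connections(
    net: BinaryNetwork | MeanNetwork, rich: RichNodeSet
) -> ConnectionDecomposition:
    """Partition total edge weight into rich / feeder / local sums."""
    if isinstance(net, MeanNetwork):
        w, labels = net.weights, net.region_labels
    else:
        w, labels = net.adjacency.astype(float), net.region_labels
    unknown = [r for r in rich.rich if r not in labels]
    if unknown:
        raise ConfigurationError(f"rich labels not in network: {unknown}")
    is_rich = np.array([lab in rich.rich for lab in labels])
    iu = np.triu_indices(len(labels), 1)
    we = w[iu]
    r1, r2 = is_rich[iu[0]], is_rich[iu[1]]
    return ConnectionDecomposition(
        rich_sum=float(we[r1 & r2].sum()),
        feeder_sum=float(we[r1 ^ r2].sum()),
        local_sum=float(we[~r1 & ~r2].sum()),
    )
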