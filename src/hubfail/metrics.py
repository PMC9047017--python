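"""Binary-network graph-theory indicators: clustering and global efficiency.

Clustering of node i is c_i = 2 e_i / (k_i (k_i - 1)), the fraction of the
node's neighbour pairs that are themselves connected; nodes of degree < 2
get c_i = 0 and are kept in the network mean, so the mean stays defined on
attacked networks containing an isolated hub.  Global efficiency is the mean
inverse hop-count distance over all ordered node pairs, with unreachable
pairs contributing 0.  Both delegate to networkx.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .netbuild import BinaryNetwork


@dataclass(frozen=True)
class MetricReport:
    per_node_clustering: np.ndarray
    mean_clustering: float
    global_efficiency: float
    region_labels: tuple[str, ...]


def clustering_coefficient(net: BinaryNetwork) -> tuple[np.ndarray, float]:
    """Per-node clustering coefficients and their mean over all N nodes."""
    g = nx.from_numpy_array(net.adjacency)
    cc = nx.clustering(g)
    per_node = np.array([cc[i] for i in range(net.n_nodes)], dtype=float)
    return per_node, float(per_node.mean())


def global_efficiency(net: BinaryNetwork) -> float:
    """Mean of 1/l_ij over all pairs; disconnected pairs count as 0."""
    return float(nx.global_efficiency(nx.from_numpy_array(net.adjacency)))


def metric_report(net: BinaryNetwork) -> MetricReport:
    per_node, mean_c = clustering_coefficient(net)
    return MetricReport(
        per_node_clustering=per_node,
        mean_clustering=mean_c,
        global_efficiency=global_efficiency(net),
        region_labels=net.region_labels,
    )
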