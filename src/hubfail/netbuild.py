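"""Network construction from regional time series.

Per subject, regional BOLD-like series are correlated (Pearson), optionally
Fisher z-transformed for group-level averaging, and binarized by an absolute
correlation threshold (default 0.3, applied to raw r with a strict ``>``):
an edge exists between two regions only when their correlation exceeds the
threshold.  Negative correlations never form edges.  Group-mean networks are
the element-wise mean of subject adjacency matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .errors import ConfigurationError, DegenerateDataError

#: clipping bound so the Fisher transform stays finite
_Z_CLIP = 1.0 - 1e-7

DEFAULT_THRESHOLD = 0.3
DENSITY_WINDOW = (0.10, 0.50)


def _check_square_symmetric(m: np.ndarray, labels, what: str) -> None:
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ConfigurationError(f"{what} must be square, got shape {m.shape}")
    if len(labels) != m.shape[0]:
        raise ConfigurationError(
            f"{what}: {len(labels)} labels for {m.shape[0]} nodes"
        )
    if not np.allclose(m, m.T, atol=1e-12):
        raise ConfigurationError(f"{what} must be symmetric")


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric Pearson correlation matrix with unit diagonal."""

    values: np.ndarray
    region_labels: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(self, "region_labels", tuple(self.region_labels))
        _check_square_symmetric(self.values, self.region_labels, "correlation matrix")
        if not np.all(np.isfinite(self.values)):
            raise ConfigurationError("correlation matrix contains non-finite values")
        if not np.allclose(np.diag(self.values), 1.0, atol=1e-12):
            raise ConfigurationError("correlation matrix diagonal must be 1")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class BinaryNetwork:
    """Undirected, unweighted network on N regions (0/1 adjacency, zero diagonal)."""

    adjacency: np.ndarray
    region_labels: tuple[str, ...]
    threshold_used: float | None = None

    def __post_init__(self):
        a = np.asarray(self.adjacency)
        if not np.isin(a, (0, 1)).all():
            raise ConfigurationError("adjacency entries must be 0 or 1")
        a = a.astype(np.int8)
        object.__setattr__(self, "adjacency", a)
        object.__setattr__(self, "region_labels", tuple(self.region_labels))
        _check_square_symmetric(a, self.region_labels, "adjacency")
        if np.diag(a).any():
            raise ConfigurationError("adjacency diagonal must be zero")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)

    def to_graph(self) -> nx.Graph:
        g = nx.from_numpy_array(self.adjacency)
        return nx.relabel_nodes(g, dict(enumerate(self.region_labels)))


@dataclass(frozen=True)
class MeanNetwork:
    """Subject-wise mean of binary adjacencies; weights are edge frequencies."""

    weights: np.ndarray
    region_labels: tuple[str, ...]
    n_subjects: int

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "region_labels", tuple(self.region_labels))
        _check_square_symmetric(w, self.region_labels, "mean network")
        if w.min() < -1e-12 or w.max() > 1 + 1e-12:
            raise ConfigurationError("mean-network weights must lie in [0, 1]")
        if np.abs(np.diag(w)).max() > 1e-12:
            raise ConfigurationError("mean-network diagonal must be zero")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def strengths(self) -> np.ndarray:
        """Weighted degree (row sum) of every region."""
        return self.weights.sum(axis=1)

    def binarize(self, threshold: float = DEFAULT_THRESHOLD) -> BinaryNetwork:
        """Threshold the mean weights (strict ``>``) into a consensus network."""
        adj = (self.weights > threshold).astype(np.int8)
        np.fill_diagonal(adj, 0)
        return BinaryNetwork(adj, self.region_labels, threshold_used=threshold)


@dataclass(frozen=True)
class NetworkQCReport:
    """Pass/fail report for the network-construction rules."""

    density: float
    mean_degree: float
    degree_bound: float  # 2 ln N
    isolated_nodes: tuple[str, ...]
    connected: bool
    density_ok: bool = field(init=False)
    degree_ok: bool = field(init=False)
    no_isolated_ok: bool = field(init=False)

    def __post_init__(self):
        lo, hi = DENSITY_WINDOW
        object.__setattr__(self, "density_ok", lo <= self.density <= hi)
        object.__setattr__(self, "degree_ok", self.mean_degree > self.degree_bound)
        object.__setattr__(self, "no_isolated_ok", len(self.isolated_nodes) == 0)

    @property
    def passed(self) -> bool:
        return self.density_ok and self.degree_ok and self.no_isolated_ok


def pearson_matrix(series: np.ndarray, region_labels=None) -> CorrelationMatrix:
    """Pearson correlation matrix of a regions x time matrix.

    Every region must have at least 3 timepoints and nonzero variance;
    a flat series is reported by name.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 2:
        raise ConfigurationError(f"series must be 2-D (regions x time), got {x.ndim}-D")
    n, t = x.shape
    if t < 3:
        raise ConfigurationError(f"need at least 3 timepoints, got {t}")
    labels = tuple(region_labels) if region_labels is not None else tuple(
        f"ROI{i + 1:03d}" for i in range(n)
    )
    sd = x.std(axis=1)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        raise DegenerateDataError(
            f"zero-variance region(s): {', '.join(labels[i] for i in flat)}"
        )
    r = np.corrcoef(x)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(r, labels)


def fisher_z(r: CorrelationMatrix) -> np.ndarray:
    """Fisher z-transform (atanh) of the off-diagonal correlations.

    |r| is clipped just below 1 so the transform stays finite; the diagonal
    is set to 0 (self-correlations carry no information).
    """
    z = np.arctanh(np.clip(r.values, -_Z_CLIP, _Z_CLIP))
    np.fill_diagonal(z, 0.0)
    return z


def binarize(r: CorrelationMatrix, threshold: float = DEFAULT_THRESHOLD) -> BinaryNetwork:
    """Edge iff r_ij > threshold (strict), i != j.  Raw r is thresholded."""
    adj = (r.values > threshold).astype(np.int8)
    np.fill_diagonal(adj, 0)
    return BinaryNetwork(adj, r.region_labels, threshold_used=threshold)


def network_checks(net: BinaryNetwork | MeanNetwork) -> NetworkQCReport:
    """Density / mean-degree / isolated-node rules for a constructed network.

    density = 2E / (N(N-1)); mean degree = 2E / N; the degree rule requires
    mean degree > 2 ln N.  For a mean network, E is the total edge weight, so
    the quantities are subject-averaged.  Report-only: nothing raises.
    """
    if isinstance(net, MeanNetwork):
        w = net.weights
        labels = net.region_labels
        connected = nx.is_connected(nx.from_numpy_array((w > 0).astype(int))) if w.any() else False
    else:
        w = net.adjacency.astype(float)
        labels = net.region_labels
        connected = bool(w.any()) and nx.is_connected(nx.from_numpy_array(w))
    n = w.shape[0]
    total = w.sum() / 2.0
    deg = w.sum(axis=1)
    return NetworkQCReport(
        density=float(2.0 * total / (n * (n - 1))),
        mean_degree=float(2.0 * total / n),
        degree_bound=float(2.0 * np.log(n)),
        isolated_nodes=tuple(labels[i] for i in np.flatnonzero(deg == 0)),
        connected=connected,
    )


def group_mean_network(nets: list[BinaryNetwork]) -> MeanNetwork:
    """Element-wise mean of subject adjacency matrices (common label order)."""
    if not nets:
        raise ConfigurationError("group_mean_network needs at least one network")
    labels = nets[0].region_labels
    for k, net in enumerate(nets):
        if net.region_labels != labels:
            raise ConfigurationError(f"network {k} has mismatching region labels")
    w = np.mean([n.adjacency for n in nets], axis=0)
    return MeanNetwork(w, labels, n_subjects=len(nets))
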