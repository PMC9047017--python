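"""Eigenvector centrality by power iteration and hub (attack-target) selection.

A node's centrality is the corresponding entry of the Perron eigenvector of
the binary adjacency matrix: x = A x / lambda, so a node is central when its
neighbours are central.  The vector is computed by power iteration from the
uniform positive start vector with L2 normalization each step.  The iteration
runs on A + I: the shift leaves every eigenvector unchanged, while making the
matrix primitive for any connected graph, so the iteration cannot oscillate
between the +/-lambda pair of a bipartite component.  The reported principal
eigenvalue is the Rayleigh quotient of A itself.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .netbuild import BinaryNetwork

logger = logging.getLogger(__name__)

DEFAULT_TOL = 1e-10
DEFAULT_MAX_ITER = 1000
TOP_FRACTION = 0.10


@dataclass(frozen=True)
class CentralityVector:
    """L2-normalized eigenvector-centrality scores for every region."""

    scores: np.ndarray
    region_labels: tuple[str, ...]
    principal_eigenvalue: float
    iterations_used: int
    converged: bool

    def __post_init__(self):
        s = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", s)
        object.__setattr__(self, "region_labels", tuple(self.region_labels))
        if len(self.region_labels) != s.shape[0]:
            raise ConfigurationError("scores/labels length mismatch")


def eigenvector_centrality(
    net: BinaryNetwork,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> CentralityVector:
    """Power-iteration Perron eigenvector of the adjacency matrix.

    Starts from the uniform vector, normalizes to unit L2 norm each step and
    declares convergence when successive iterates differ by < ``tol`` in
    max-norm.  Non-convergence is logged and returned with
    ``converged=False`` rather than raised.
    """
    a = net.adjacency.astype(float)
    n = a.shape[0]
    if n < 2:
        raise ConfigurationError("eigenvector centrality needs at least 2 nodes")
    if not a.any():
        raise ConfigurationError("eigenvector centrality needs at least one edge")
    x = np.full(n, 1.0 / math.sqrt(n))
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        y = a @ x + x  # (A + I) x: spectral shift, same eigenvectors
        x_new = y / np.linalg.norm(y)
        if np.max(np.abs(x_new - x)) < tol:
            x = x_new
            converged = True
            break
        x = x_new
    if not converged:
        logger.warning(
            "power iteration did not converge in %d iterations (tol=%g); "
            "disconnected or oscillatory structure?", max_iter, tol
        )
    lam = float(x @ a @ x)  # Rayleigh quotient of A (unit-norm x)
    return CentralityVector(
        scores=x,
        region_labels=net.region_labels,
        principal_eigenvalue=lam,
        iterations_used=iterations,
        converged=converged,
    )


def _ranked_indices(cv: CentralityVector) -> np.ndarray:
    # stable sort on descending score -> ties broken by label (= index) order
    return np.argsort(-cv.scores, kind="stable")


def rank_hubs(cv: CentralityVector, top_fraction: float = TOP_FRACTION) -> list[tuple[str, float]]:
    """Top ceil(top_fraction * N) regions by score, descending, ties by label order."""
    if not 0 < top_fraction <= 1:
        raise ConfigurationError(f"top_fraction must be in (0, 1], got {top_fraction}")
    n_top = math.ceil(top_fraction * len(cv.region_labels))
    order = _ranked_indices(cv)[:n_top]
    return [(cv.region_labels[i], float(cv.scores[i])) for i in order]


def select_attack_target(cv: CentralityVector) -> str:
    """The region with the highest centrality (ties -> first label in order)."""
    return cv.region_labels[int(_ranked_indices(cv)[0])]
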