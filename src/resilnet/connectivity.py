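"""Global connectivity measures of a partial-correlation network.

Three group-level summaries: average node strength (mean over nodes of the
summed absolute edge weights), average expected influence (same with signed
weights), and average shortest path length with edge distance 1/|w| (the
standard convention in weighted psychological-network path analysis; an
absent edge is non-traversable). Under this convention uniformly stronger
edges shorten every path, so "stronger connectivity <-> shorter paths" holds
by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import shortest_path

__all__ = [
    "ConnectivityMetrics",
    "node_strength",
    "expected_influence",
    "average_shortest_path_length",
    "connectivity_metrics",
]


@dataclass
class ConnectivityMetrics:
    strength_per_node: np.ndarray
    ei_per_node: np.ndarray
    avg_strength: float
    avg_expected_influence: float
    avg_shortest_path_length: float
    n_disconnected_pairs: int
    distance_convention: str

    def as_dict(self) -> dict:
        return {
            "avg_strength": self.avg_strength,
            "avg_expected_influence": self.avg_expected_influence,
            "avg_shortest_path_length": self.avg_shortest_path_length,
            "n_disconnected_pairs": self.n_disconnected_pairs,
            "distance_convention": self.distance_convention,
            "strength_per_node": self.strength_per_node.tolist(),
            "ei_per_node": self.ei_per_node.tolist(),
        }


def _check_weights(W):
    W = np.asarray(W, float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("weight matrix must be square")
    if not np.allclose(W, W.T, atol=1e-10):
        raise ValueError("weight matrix must be symmetric")
    if np.abs(np.diagonal(W)).max(initial=0.0) > 1e-12:
        raise ValueError("weight matrix must have zero diagonal")
    return W


def node_strength(W):
    """Per-node sum of absolute incident edge weights, and its average."""
    W = _check_weights(W)
    s = np.abs(W).sum(axis=1)
    return s, float(s.mean())


def expected_influence(W):
    """Per-node signed sum of incident edge weights, and its average."""
    W = _check_weights(W)
    e = W.sum(axis=1)
    return e, float(e.mean())


def average_shortest_path_length(W, convention: str = "inverse_abs",
                                 pairs: str = "unordered"):
    """Mean shortest-path distance over connected node pairs.

    Edge distance is 1/|w| ("inverse_abs", default) or -log|w| ("neg_log",
    defined for |w| < 1). Disconnected pairs are excluded from the mean and
    counted; a network with no finite pair raises.

    Returns ``(mean_distance, n_disconnected_pairs)``.
    """
    W = _check_weights(W)
    k = W.shape[0]
    if pairs not in ("unordered", "ordered"):
        raise ValueError(f"unknown pair convention {pairs!r}")
    with np.errstate(divide="ignore"):
        if convention == "inverse_abs":
            D = np.where(W != 0, 1.0 / np.abs(W), np.inf)
        elif convention == "neg_log":
            if np.abs(W).max(initial=0.0) >= 1.0:
                raise ValueError("neg_log distance needs |w| < 1")
            D = np.where(W != 0, -np.log(np.abs(W)), np.inf)
        else:
            raise ValueError(f"unknown distance convention {convention!r}")
    G = np.where(np.isfinite(D), D, 0.0)
    dist = shortest_path(G, method="D", directed=False, unweighted=False)
    iu = np.triu_indices(k, 1)
    d = dist[iu]
    finite = np.isfinite(d)
    n_disc = int(np.count_nonzero(~finite))
    if not finite.any():
        raise ValueError("network is fully disconnected: no finite pair")
    # ordered vs unordered averaging coincides for a symmetric network;
    # only the disconnection count doubles.
    if pairs == "ordered":
        n_disc *= 2
    return float(d[finite].mean()), n_disc


def connectivity_metrics(W, convention: str = "inverse_abs",
                         pairs: str = "unordered") -> ConnectivityMetrics:
    """All three global connectivity measures of one network."""
    s, avg_s = node_strength(W)
    e, avg_e = expected_influence(W)
    apl, n_disc = average_shortest_path_length(W, convention, pairs)
    return ConnectivityMetrics(
        strength_per_node=s,
        ei_per_node=e,
        avg_strength=avg_s,
        avg_expected_influence=avg_e,
        avg_shortest_path_length=apl,
        n_disconnected_pairs=n_disc,
        distance_convention=convention,
    )
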