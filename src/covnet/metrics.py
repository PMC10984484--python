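"""Global and nodal measures of signed covariance networks, and hubs.

All measures treat the network as undirected and signed, with a zero
diagonal.  Strengths are reported separately for positive and negative
edges (the negative strength as a magnitude), and the clustering
coefficient is the signed generalization that weights each triangle by the
product of its three (max-normalized) edge weights, so triangles whose
sign product is negative count against a node's clustering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .networks import CovarianceNetwork, ThresholdedNetwork, n_unique_edges

Network = CovarianceNetwork | ThresholdedNetwork


def _weights_of(net) -> np.ndarray:
    return np.asarray(net.weights if hasattr(net, "weights") else net, dtype=float)


def density(net: Network) -> tuple[int, float]:
    """Connection count and fraction of the possible unordered edges."""
    w = _weights_of(net)
    iu = np.triu_indices(w.shape[0], k=1)
    edge_count = int(np.count_nonzero(w[iu]))
    return edge_count, edge_count / n_unique_edges(w.shape[0])


def nodal_degree(net: Network) -> np.ndarray:
    """Number of nonzero connections per region."""
    w = _weights_of(net)
    return np.count_nonzero(w, axis=1).astype(int)


def nodal_strength_signed(net: Network) -> tuple[np.ndarray, np.ndarray]:
    """Positive and negative strength per region.

    Positive strength is the sum of positive edge weights at the node;
    negative strength is the sum of magnitudes of the negative weights
    (reported as a nonnegative quantity).
    """
    w = _weights_of(net)
    return np.maximum(w, 0.0).sum(axis=1), np.maximum(-w, 0.0).sum(axis=1)


def clustering_signed(net: Network) -> np.ndarray:
    """Signed weighted clustering coefficient per region.

    With weights normalized by the network-wide maximum absolute weight
    (w_hat = w / max|w|), the coefficient at node i is

        C_i = sum_{j != i} sum_{k != i,j} w_hat_ij * w_hat_jk * w_hat_ki
              / sum_{j != i} sum_{k != i,j} |w_hat_ij * w_hat_ki|

    i.e. the total signed triangle weight around i relative to the weight
    of the open triples centred at i.  C_i lies in [-1, 1]; nodes with no
    open triples get 0.
    """
    w = _weights_of(net).copy()
    np.fill_diagonal(w, 0.0)
    wmax = np.abs(w).max()
    if wmax > 0:
        w = w / wmax
    # numerator: diag of w^3 counts ordered (j, k) pairs of closed triangles
    numer = np.einsum("ij,jk,ki->i", w, w, w)
    aw = np.abs(w)
    s_abs = aw.sum(axis=1)
    # ordered open triples centred at i: (sum_j |w_ij|)^2 - sum_j |w_ij|^2
    denom = s_abs**2 - (aw**2).sum(axis=1)
    out = np.zeros(w.shape[0])
    nz = denom > 0
    out[nz] = numer[nz] / denom[nz]
    return out


def identify_hubs(
    metric: np.ndarray, quantile: float = 0.25, region_labels=None
) -> np.ndarray:
    """Indices (or labels) of the top-``quantile`` regions by a nodal metric.

    Returns exactly ceil(n * quantile) regions — 7 for 27 regions at the
    top-quartile rule — ranked descending.  Ties are broken by region index
    order, so the result is deterministic.
    """
    metric = np.asarray(metric, dtype=float)
    if not 0 < quantile <= 1:
        raise ValueError("quantile must be in (0, 1]")
    k = math.ceil(len(metric) * quantile)
    order = np.argsort(-metric, kind="stable")[:k]
    if region_labels is not None:
        return np.asarray([region_labels[i] for i in order])
    return order


@dataclass(frozen=True)
class NodalMetrics:
    """Per-region measures of one (thresholded or full) network."""

    region_labels: tuple[str, ...]
    degree: np.ndarray
    strength_pos: np.ndarray
    strength_neg: np.ndarray
    clustering: np.ndarray

    @property
    def strength_abs(self) -> np.ndarray:
        """Cumulative strength: sum of absolute edge weights per region."""
        return self.strength_pos + self.strength_neg

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "degree": self.degree,
                "strength_pos": self.strength_pos,
                "strength_neg": self.strength_neg,
                "strength_abs": self.strength_abs,
                "clustering": self.clustering,
            },
            index=list(self.region_labels),
        )


def nodal_metrics(net: Network) -> NodalMetrics:
    s_pos, s_neg = nodal_strength_signed(net)
    return NodalMetrics(
        region_labels=tuple(net.region_labels),
        degree=nodal_degree(net),
        strength_pos=s_pos,
        strength_neg=s_neg,
        clustering=clustering_signed(net),
    )


def hubs(
    net: Network, mode: str = "degree", quantile: float = 0.25
) -> np.ndarray:
    """Hub regions: top quantile by degree or cumulative absolute strength."""
    m = nodal_metrics(net)
    if mode == "degree":
        metric = m.degree
    elif mode == "strength":
        metric = m.strength_abs
    else:
        raise ValueError("mode must be 'degree' or 'strength'")
    return identify_hubs(metric, quantile, region_labels=net.region_labels)
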