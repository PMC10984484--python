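"""Group covariance networks: estimation, edge significance, thresholding.

A metabolic covariance network is a group-level construct: the edge between
regions i and j is the Pearson correlation of their SUVR values across the
animals of one homogeneous group.  Edge-level significance comes from a
random-shift null model — each region's values are permuted independently
across animals, destroying inter-regional covariance while preserving every
marginal — and networks are thresholded by zeroing non-significant edges
while keeping the signed weights of the significant ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import connected_components

from .data import RegionalUptakeTable


def n_unique_edges(n_regions: int) -> int:
    """Number of unordered region pairs (unique undirected edges)."""
    return n_regions * (n_regions - 1) // 2


def compute_suvr(region_activity: float, cerebellum_activity: float):
    """Standardized uptake value ratio: regional activity over cerebellar
    reference activity (both in Bq/ml); dimensionless."""
    region_activity = np.asarray(region_activity, dtype=float)
    cerebellum_activity = np.asarray(cerebellum_activity, dtype=float)
    if np.any(cerebellum_activity <= 0):
        raise ValueError("cerebellum reference activity must be positive")
    if np.any(region_activity <= 0):
        raise ValueError("region activity must be positive")
    out = region_activity / cerebellum_activity
    return float(out) if out.ndim == 0 else out


def _zscore_columns(values: np.ndarray, region_labels) -> np.ndarray:
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        names = [region_labels[j] for j in zero]
        raise ValueError(f"zero-variance region(s): {names}; cannot z-score")
    return (values - mean) / sd


def zscore_by_region(table: RegionalUptakeTable) -> np.ndarray:
    """Z-score each region across animals (sample SD, n-1 denominator).

    Returns the z-scored matrix rather than a new table: z-scores are
    centred at 0 and therefore not valid SUVR values.
    """
    return _zscore_columns(table.values, table.region_labels)


@dataclass(frozen=True)
class CovarianceNetwork:
    """Region x region Pearson correlation network for one group."""

    group_id: str
    region_labels: tuple[str, ...]
    weights: np.ndarray = field(repr=False)
    n_animals: int = 0
    edge_p: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        p = len(self.region_labels)
        if w.shape != (p, p):
            raise ValueError("weights must be square and match region_labels")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("weights must be symmetric")
        if np.any(np.abs(w) > 1 + 1e-12):
            raise ValueError("Pearson weights must lie in [-1, 1]")
        if np.any(np.diag(w) != 0):
            raise ValueError("diagonal must be 0 (self-correlations carry no information)")
        if self.edge_p is not None:
            ep = np.asarray(self.edge_p, dtype=float)
            object.__setattr__(self, "edge_p", ep)
            if ep.shape != (p, p):
                raise ValueError("edge_p must match weights in shape")

    @property
    def n_regions(self) -> int:
        return len(self.region_labels)

    @property
    def n_edges(self) -> int:
        return n_unique_edges(self.n_regions)

    def edge_values(self) -> np.ndarray:
        """The n*(n-1)/2 unique edge weights (upper triangle, row-major)."""
        iu = np.triu_indices(self.n_regions, k=1)
        return self.weights[iu]

    def with_edge_p(self, edge_p: np.ndarray) -> "CovarianceNetwork":
        return CovarianceNetwork(
            group_id=self.group_id,
            region_labels=self.region_labels,
            weights=self.weights,
            n_animals=self.n_animals,
            edge_p=edge_p,
        )


@dataclass(frozen=True)
class ThresholdedNetwork:
    """Covariance network with non-significant edges zeroed."""

    base: CovarianceNetwork
    level: float
    weights: np.ndarray = field(repr=False)
    fragmented: bool = False

    @property
    def region_labels(self) -> tuple[str, ...]:
        return self.base.region_labels

    @property
    def n_regions(self) -> int:
        return self.base.n_regions

    def edge_values(self, nonzero_only: bool = False) -> np.ndarray:
        iu = np.triu_indices(self.n_regions, k=1)
        vals = self.weights[iu]
        return vals[vals != 0] if nonzero_only else vals


def covariance_network(table: RegionalUptakeTable) -> CovarianceNetwork:
    """Pearson correlation network across animals within one group.

    The diagonal is set to 0.  Because Pearson r is affine-invariant the
    result is identical whether computed on raw or z-scored SUVR.
    """
    z = zscore_by_region(table)
    n = table.n_animals
    w = (z.T @ z) / (n - 1)
    w = np.clip((w + w.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(w, 0.0)
    return CovarianceNetwork(
        group_id=table.group_id,
        region_labels=table.region_labels,
        weights=w,
        n_animals=n,
    )


def _null_correlations(
    z: np.ndarray, n_perm: int, rng: np.random.Generator, chunk: int = 500
):
    """Yield chunks of null correlation matrices under the random-shift null.

    Each null iterate permutes every region's column independently over
    animals and recomputes the full correlation matrix.
    """
    n, p = z.shape
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        # independent permutation per (iterate, column) via argsort of noise
        idx = np.argsort(rng.random((m, n, p)), axis=1)
        zp = z[idx, np.arange(p)[None, None, :]]
        yield np.einsum("mij,mik->mjk", zp, zp) / (n - 1)
        done += m


def edge_significance(
    table: RegionalUptakeTable,
    n_perm: int = 10_000,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Per-edge permutation p-values under the random-shift null model.

    Positive and negative correlations are handled separately: an edge with
    empirical r > 0 is compared against the positive part of its null
    distribution, an edge with r < 0 against the negative part, i.e.

        p = (1 + #{same-sign nulls with |null r| >= |empirical r|})
            / (1 + #{same-sign nulls})

    which is calibrated at the nominal level (each sign tail is a
    conditional one-sided test) and returns p = 1 for an edge with r = 0.
    The diagonal is reported as 1.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for a usable p-value resolution")
    rng = np.random.default_rng(seed)
    z = zscore_by_region(table)
    n, p = z.shape
    emp = (z.T @ z) / (n - 1)
    np.fill_diagonal(emp, 0.0)

    exceed = np.zeros((p, p), dtype=np.int64)  # same-sign nulls at least as extreme
    same_sign = np.zeros((p, p), dtype=np.int64)
    pos_emp = emp > 0
    for null in _null_correlations(z, n_perm, rng):
        null_pos = null > 0
        sign_match = np.where(pos_emp[None], null_pos, null < 0)
        same_sign += sign_match.sum(axis=0)
        exceed += (sign_match & (np.abs(null) >= np.abs(emp)[None])).sum(axis=0)

    pvals = (1.0 + exceed) / (1.0 + same_sign)
    pvals[emp == 0] = 1.0
    np.fill_diagonal(pvals, 1.0)
    return pvals


def threshold_network(net: CovarianceNetwork, level: float) -> ThresholdedNetwork:
    """Zero edges whose permutation p-value is >= ``level``.

    Significant edges keep their signed weights.  The ``fragmented`` flag is
    set when any node or node group is disconnected from the rest of the
    network after thresholding.
    """
    if net.edge_p is None:
        raise ValueError("network has no edge p-values; run edge_significance first")
    if not 0 < level <= 1:
        raise ValueError("level must be in (0, 1]")
    # level = 1 retains everything (p-values live in (0, 1])
    keep = net.edge_p < level if level < 1.0 else np.ones_like(net.edge_p, dtype=bool)
    w = np.where(keep, net.weights, 0.0)
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 0.0)
    n_comp, _ = connected_components(np.abs(w) > 0, directed=False)
    return ThresholdedNetwork(base=net, level=level, weights=w, fragmented=n_comp > 1)


def estimate_group_network(
    table: RegionalUptakeTable,
    levels=(0.05, 0.01),
    n_perm: int = 10_000,
    seed: int | np.random.Generator | None = None,
) -> tuple[CovarianceNetwork, dict[float, ThresholdedNetwork]]:
    """Convenience wrapper: network + edge p-values + thresholded variants."""
    net = covariance_network(table)
    net = net.with_edge_p(edge_significance(table, n_perm=n_perm, seed=seed))
    thresholded = {level: threshold_network(net, level) for level in levels}
    for level, tn in thresholded.items():
        if tn.fragmented:
            warnings.warn(
                f"group {net.group_id!r}: network thresholded at p < {level} is "
                "fragmented (some nodes disconnected)",
                stacklevel=2,
            )
    return net, thresholded
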