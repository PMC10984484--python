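"""Signed-modularity community detection and multiresolution consensus.

Modularity maximization runs on the *unthresholded* signed correlation
network using the asymmetric positive/negative quality function common for
correlation-derived networks: positive within-community weight is rewarded
relative to a configuration-model expectation and normalized by the total
positive weight, while negative within-community weight is penalized with
the softer 1/(v+ + v-) normalization,

    Q(gamma) = (1/v+) sum_ij [w+_ij - gamma e+_ij] d(c_i, c_j)
             - (1/(v+ + v-)) sum_ij [w-_ij - gamma e-_ij] d(c_i, c_j)

with e±_ij = s±_i s±_j / v± and v± the total positive/negative weight.
The resolution parameter gamma scales the expected-weight term: small
gamma favours coarse partitions, large gamma fine ones.

Multiresolution consensus clustering (MRCC) samples an ensemble of Louvain
partitions across the informative gamma range, summarizes them in a
co-assignment matrix (probability a region pair shares a community), and
recursively extracts a consensus partition: at each split the co-assignment
submatrix is tested against a permutation-model local null at significance
alpha, and only significant structure is split further.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import adjusted_mutual_info_score

from .networks import CovarianceNetwork


# ---------------------------------------------------------------------------
# partitions


def _normalize_labels(labels: Sequence[int]) -> np.ndarray:
    """Relabel communities 1..K in order of first appearance."""
    labels = np.asarray(labels)
    _, inv = np.unique(labels, return_inverse=True)
    first_seen = {}
    out = np.empty(len(labels), dtype=int)
    next_id = 1
    for i, l in enumerate(inv):
        if l not in first_seen:
            first_seen[l] = next_id
            next_id += 1
        out[i] = first_seen[l]
    return out


@dataclass(frozen=True)
class Partition:
    """Community labels per region (contiguous, 1-based)."""

    region_labels: tuple[str, ...]
    labels: np.ndarray = field(repr=False)
    gamma: float | None = None

    def __post_init__(self) -> None:
        labels = _normalize_labels(self.labels)
        if len(labels) != len(self.region_labels):
            raise ValueError("labels length must match region_labels")
        object.__setattr__(self, "labels", labels)

    @property
    def n_communities(self) -> int:
        return int(self.labels.max()) if len(self.labels) else 0

    def members(self, community: int) -> list[str]:
        return [r for r, l in zip(self.region_labels, self.labels) if l == community]

    def as_dict(self) -> dict[str, int]:
        return {r: int(l) for r, l in zip(self.region_labels, self.labels)}


def ami(p1: Partition, p2: Partition) -> float:
    """Adjusted mutual information between two partitions of the same regions.

    Chance-corrected under the permutation model with the arithmetic-mean
    entropy normalizer; 1.0 iff the partitions are identical up to
    relabeling, and about 0 for independent partitions.
    """
    if p1.region_labels != p2.region_labels:
        raise ValueError("partitions must be over the same regions, in the same order")
    return float(
        adjusted_mutual_info_score(p1.labels, p2.labels, average_method="arithmetic")
    )


def coclassification(partitions: Sequence[Partition]) -> tuple[np.ndarray, np.ndarray]:
    """Co-classification matrix of a set of partitions.

    Entry (i, j) is the fraction of partitions assigning regions i and j to
    the same community (diagonal 1).  The second return value is the
    per-region mean co-classification excluding the diagonal.
    """
    if len(partitions) < 2:
        raise ValueError("need at least 2 partitions")
    regions = partitions[0].region_labels
    for p in partitions[1:]:
        if p.region_labels != regions:
            raise ValueError("all partitions must cover the same regions")
    n = len(regions)
    co = np.zeros((n, n))
    for p in partitions:
        co += p.labels[:, None] == p.labels[None, :]
    co /= len(partitions)
    mean = (co.sum(axis=1) - 1.0) / (n - 1)
    return co, mean


# ---------------------------------------------------------------------------
# signed modularity + generalized Louvain


def signed_modularity_matrix(weights: np.ndarray, gamma: float = 1.0) -> np.ndarray:
    """Modularity matrix B such that Q = sum_{ij in same community} B_ij."""
    w = np.asarray(weights, dtype=float)
    wp = np.maximum(w, 0.0)
    wn = np.maximum(-w, 0.0)
    vp = wp.sum()
    vn = wn.sum()
    B = np.zeros_like(w)
    if vp > 0:
        sp = wp.sum(axis=1)
        B += (wp - gamma * np.outer(sp, sp) / vp) / vp
    if vn > 0:
        sn = wn.sum(axis=1)
        B -= (wn - gamma * np.outer(sn, sn) / vn) / (vp + vn)
    return (B + B.T) / 2.0


def partition_quality(weights: np.ndarray, labels, gamma: float = 1.0) -> float:
    """Signed modularity Q of a labeling (diagonal terms included; they are
    partition-independent, so comparisons between partitions are unaffected)."""
    B = signed_modularity_matrix(weights, gamma)
    labels = np.asarray(labels)
    same = labels[:, None] == labels[None, :]
    return float(B[same].sum())


def _local_moves(B: np.ndarray, labels: np.ndarray, rng: np.random.Generator) -> bool:
    """Greedy node moves on modularity matrix B until no move improves Q.

    Returns True if any move was made.  Gain of moving node i to community c
    is 2 * (sum of B[i, members(c)] - sum of B[i, members(current) - {i}]).
    """
    n = B.shape[0]
    moved_any = False
    improved = True
    while improved:
        improved = False
        for i in rng.permutation(n):
            # B[i] summed into each community; one spare empty slot so a
            # node can always split off into a singleton
            comm_sum = np.zeros(labels.max() + 2)
            np.add.at(comm_sum, labels, B[i])
            current = labels[i]
            comm_sum[current] -= B[i, i]
            gain = comm_sum - comm_sum[current]
            best = int(np.argmax(gain))
            if gain[best] > 1e-12 and best != current:
                labels[i] = best
                improved = True
                moved_any = True
    return moved_any


def _louvain_once(B: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One greedy optimization from all-singletons: alternate node-level
    moves and community-level (aggregated) moves until neither improves Q."""
    return _louvain_once_from(B, np.arange(B.shape[0]), rng)


def _quality_of(B: np.ndarray, labels: np.ndarray) -> float:
    return float(B[labels[:, None] == labels[None, :]].sum())


def _perturb(labels: np.ndarray, rng: np.random.Generator, frac: float = 0.3) -> np.ndarray:
    out = labels.copy()
    n = len(out)
    k = out.max() + 1
    pick = rng.random(n) < frac
    out[pick] = rng.integers(0, k + 1, pick.sum())  # existing or one new community
    return out


def louvain_signed(
    net: CovarianceNetwork | np.ndarray,
    gamma: float = 1.0,
    seed: int | np.random.Generator | None = None,
    n_restarts: int = 10,
    ils_rounds: int = 6,
) -> Partition:
    """Signed-modularity Louvain partition of an (unthresholded) network.

    Runs ``n_restarts`` greedy optimizations with shuffled move orders from
    the seeded generator; each restart is polished by ``ils_rounds`` of
    iterated local search (perturb a random subset of nodes, re-optimize,
    keep if Q improves).  Returns the best-Q partition, ties broken by
    first-found.  Set ``ils_rounds=0`` for fast single-pass optimization
    (used when sampling diverse ensembles).
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    if isinstance(net, CovarianceNetwork):
        weights = net.weights
        region_labels = net.region_labels
    else:
        weights = np.asarray(net, dtype=float)
        region_labels = tuple(f"n{i}" for i in range(weights.shape[0]))
    rng = np.random.default_rng(seed)
    if not np.any(weights):
        warnings.warn("all-zero network: returning a single community", stacklevel=2)
        return Partition(region_labels, np.ones(weights.shape[0], dtype=int), gamma=gamma)
    B = signed_modularity_matrix(weights, gamma)
    best_labels, best_q = None, -np.inf
    for _ in range(max(1, n_restarts)):
        labels = _louvain_once(B, rng)
        q = _quality_of(B, labels)
        for _ in range(ils_rounds):
            trial = _louvain_once_from(B, _perturb(labels, rng), rng)
            tq = _quality_of(B, trial)
            if tq > q + 1e-12:
                labels, q = trial, tq
        if q > best_q + 1e-12:
            best_q, best_labels = q, labels
    return Partition(region_labels, best_labels + 1, gamma=gamma)


def _louvain_once_from(B: np.ndarray, start: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Node/community move alternation starting from a given labeling."""
    n = B.shape[0]
    labels = start.copy()
    while True:
        moved = _local_moves(B, labels, rng)
        _, labels = np.unique(labels, return_inverse=True)
        k = labels.max() + 1
        moved_agg = False
        if k > 1:
            S = np.zeros((n, k))
            S[np.arange(n), labels] = 1.0
            agg = S.T @ B @ S
            agg_labels = np.arange(k)
            moved_agg = _local_moves(agg, agg_labels, rng)
            if moved_agg:
                labels = agg_labels[labels]
        if not (moved or moved_agg):
            return labels


# ---------------------------------------------------------------------------
# multiresolution consensus clustering


@dataclass(frozen=True)
class ConsensusResult:
    """Output of multiresolution consensus clustering."""

    ensemble_size: int
    coassignment: np.ndarray = field(repr=False)
    consensus: Partition = None
    hierarchy: tuple[Partition, ...] = ()
    alpha: float = 0.05
    gamma_range: tuple[float, float] = (0.0, 1.0)

    def hierarchy_json(self) -> str:
        levels = [
            {"level": k, "n_communities": p.n_communities, "labels": p.as_dict()}
            for k, p in enumerate(self.hierarchy)
        ]
        return json.dumps(
            {
                "alpha": self.alpha,
                "ensemble_size": self.ensemble_size,
                "gamma_range": list(self.gamma_range),
                "levels": levels,
            },
            indent=2,
        )


def gamma_range(
    weights: np.ndarray,
    gamma_min: float = 1e-3,
    attractive_quantile: float = 0.95,
) -> tuple[float, float]:
    """Informative resolution interval for a signed network.

    A positive pair (i, j) is *attractive* at resolution gamma while
    w+_ij > gamma * s+_i s+_j / v+, i.e. up to
    gamma_ij = w+_ij v+ / (s+_i s+_j).  The interval runs from near zero
    (where optimization returns the coarsest partitions) to the
    ``attractive_quantile`` of the per-pair limits — beyond that scale
    essentially no pair remains attractive and modularity can no longer
    justify merges, so finer gammas add no informative partitions.  (With
    the asymmetric signed quality function a literal all-singletons
    partition need not exist at any finite gamma, so the classical
    "smallest gamma giving all singletons" endpoint is not well defined.)
    """
    w = np.asarray(weights, dtype=float)
    wp = np.maximum(w, 0.0)
    np.fill_diagonal(wp, 0.0)
    vp = wp.sum()
    if vp <= 0:
        return gamma_min, 1.0
    sp = wp.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        limits = wp * vp / np.outer(sp, sp)
    vals = limits[wp > 0]
    return gamma_min, float(np.quantile(vals, attractive_quantile))


def sample_partition_ensemble(
    weights: np.ndarray,
    n_partitions: int,
    rng: np.random.Generator,
    gammas: tuple[float, float] | None = None,
    restarts_per_sample: int = 1,
    sampling: str = "uniform",
) -> list[Partition]:
    """Louvain partition ensemble across the informative gamma range.

    ``sampling='uniform'`` draws gammas i.i.d. uniform over the interval,
    so each resolution scale contributes to the co-assignment matrix in
    proportion to its gamma-measure; ``sampling='grid'`` uses an evenly
    spaced grid instead (deterministic gamma placement).
    """
    if gammas is None:
        gammas = gamma_range(weights)
    g_lo, g_hi = gammas
    if sampling == "uniform":
        gs = np.sort(rng.uniform(g_lo, g_hi, n_partitions))
    elif sampling == "grid":
        gs = np.linspace(g_lo, g_hi, n_partitions)
    else:
        raise ValueError("sampling must be 'uniform' or 'grid'")
    return [
        louvain_signed(
            weights, gamma=max(g, 1e-6), seed=rng,
            n_restarts=restarts_per_sample, ils_rounds=0,
        )
        for g in gs
    ]


def _coassignment_from_labels(label_matrix: np.ndarray) -> np.ndarray:
    """Co-assignment matrix from an (ensemble x nodes) label matrix."""
    m, n = label_matrix.shape
    co = np.zeros((n, n))
    for row in label_matrix:
        co += row[:, None] == row[None, :]
    return co / m


def _null_coassignment_threshold(
    label_matrix: np.ndarray, alpha: float, rng: np.random.Generator, n_null: int = 1000
) -> float:
    """(1 - alpha) quantile of the permutation-model null co-assignment.

    Under independent label permutations within each ensemble partition, the
    co-assignment of any fixed node pair is the mean over partitions of
    Bernoulli(p0_m), where p0_m = sum_k n_k (n_k - 1) / (n (n - 1)) for the
    community sizes of partition m.  The null is sampled directly from that
    representation.
    """
    m, n = label_matrix.shape
    if n < 2:
        return 1.0
    p0 = np.empty(m)
    for i, row in enumerate(label_matrix):
        _, counts = np.unique(row, return_counts=True)
        p0[i] = (counts * (counts - 1)).sum() / (n * (n - 1))
    draws = (rng.random((n_null, m)) < p0[None, :]).mean(axis=1)
    return float(np.quantile(draws, 1.0 - alpha))


def _consensus_split(
    co_sub: np.ndarray, threshold: float, rng: np.random.Generator
) -> np.ndarray:
    """Cluster a co-assignment submatrix against its null threshold."""
    A = co_sub - threshold
    np.fill_diagonal(A, 0.0)
    if not np.any(A > 0):
        return np.ones(co_sub.shape[0], dtype=int)
    labels = _louvain_once(A, rng)
    for _ in range(4):  # a few restarts for stability on small blocks
        alt = _louvain_once(A, rng)
        same = alt[:, None] == alt[None, :]
        if A[same].sum() > A[labels[:, None] == labels[None, :]].sum() + 1e-12:
            labels = alt
    return _normalize_labels(labels)


def mrcc(
    net: CovarianceNetwork | np.ndarray,
    n_partitions: int = 10_000,
    alpha: float = 0.05,
    seed: int | np.random.Generator | None = None,
    gammas: tuple[float, float] | None = None,
    n_null: int = 1000,
) -> ConsensusResult:
    """Multiresolution consensus clustering of a signed network.

    1.  Locate the informative gamma interval (coarsest partition to
        all-singletons) by bisection.
    2.  Sample ``n_partitions`` Louvain partitions across the interval
        (event-style adaptive refinement).
    3.  Build the co-assignment matrix.
    4.  Recursively split node sets whose co-assignment exceeds the
        permutation-model local null at significance ``alpha``; the leaves
        form the consensus partition and each recursion depth contributes a
        level to the hierarchy (coarse to fine).
    """
    if n_partitions < 100:
        raise ValueError("n_partitions must be >= 100")
    if isinstance(net, CovarianceNetwork):
        weights = net.weights
        region_labels = net.region_labels
    else:
        weights = np.asarray(net, dtype=float)
        region_labels = tuple(f"n{i}" for i in range(weights.shape[0]))
    n = weights.shape[0]
    rng = np.random.default_rng(seed)

    if not np.any(weights):
        warnings.warn("degenerate (all-zero) network: single-community consensus",
                      stacklevel=2)
        single = Partition(region_labels, np.ones(n, dtype=int))
        return ConsensusResult(
            ensemble_size=0, coassignment=np.ones((n, n)), consensus=single,
            hierarchy=(single,), alpha=alpha, gamma_range=(0.0, 0.0),
        )

    if gammas is None:
        gammas = gamma_range(weights)
    ensemble = sample_partition_ensemble(weights, n_partitions, rng, gammas=gammas)
    label_matrix = np.vstack([p.labels for p in ensemble])
    co = _coassignment_from_labels(label_matrix)

    # consensus: one global consensus-clustering pass of the co-assignment
    # matrix against the whole-ensemble permutation null — the community
    # structure supported across the full resolution range
    thr_global = _null_coassignment_threshold(label_matrix, alpha, rng, n_null=n_null)
    consensus_labels = _consensus_split(co, thr_global, rng)
    consensus = Partition(region_labels, consensus_labels)

    # hierarchy: recursive within-cluster refinement against local nulls,
    # exposing finer, locally persistent scales below the consensus
    def try_split(nodes: np.ndarray) -> list[np.ndarray]:
        if len(nodes) == 1:
            return [nodes]
        thr = _null_coassignment_threshold(
            label_matrix[:, nodes], alpha, rng, n_null=n_null
        )
        parts = _consensus_split(co[np.ix_(nodes, nodes)], thr, rng)
        if parts.max() == 1:
            return [nodes]
        return [nodes[parts == c] for c in range(1, parts.max() + 1)]

    groups: list[tuple[np.ndarray, bool]] = [
        (np.flatnonzero(consensus_labels == c), False)
        for c in range(1, consensus_labels.max() + 1)
    ]
    level_partitions: list[np.ndarray] = []

    def record_level() -> None:
        labels = np.zeros(n, dtype=int)
        for c, (nodes, _) in enumerate(groups, start=1):
            labels[nodes] = c
        level_partitions.append(labels)

    record_level()  # the consensus level itself
    while True:
        new_groups: list[tuple[np.ndarray, bool]] = []
        changed = False
        for nodes, frozen in groups:
            if frozen:
                new_groups.append((nodes, True))
                continue
            parts = try_split(nodes)
            if len(parts) == 1:
                new_groups.append((nodes, True))
            else:
                changed = True
                new_groups.extend((p, False) for p in parts)
        if not changed:
            break
        groups = new_groups
        record_level()

    hierarchy = [Partition(region_labels, np.ones(n, dtype=int))]
    hierarchy += [Partition(region_labels, lv) for lv in level_partitions]
    return ConsensusResult(
        ensemble_size=n_partitions,
        coassignment=co,
        consensus=consensus,
        hierarchy=tuple(hierarchy),
        alpha=alpha,
        gamma_range=tuple(gammas),
    )
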