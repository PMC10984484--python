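"""Between-group statistics on covariance networks.

Edge-weight and nodal-metric distributions are compared with two-sample
Kolmogorov-Smirnov tests.  Edge-level differences are assessed with a
group-label permutation test: the statistic at each edge is the difference
of the two groups' Pearson correlations, and the null is built by randomly
reassigning the pooled animals to two pseudo-groups of the original sizes
and recomputing both covariance networks at every permutation.  Multiple
comparisons over the edges are controlled with Benjamini-Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data import RegionalUptakeTable
from .metrics import nodal_metrics
from .networks import (
    CovarianceNetwork,
    covariance_network,
    edge_significance,
    threshold_network,
)


def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test.

    Returns (D, p) where D is the supremum distance between the two
    empirical CDFs and p comes from the asymptotic two-sample KS
    distribution.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    res = stats.ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(res.pvalue)


def fdr_bh(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR control.

    Returns (rejected mask, adjusted p-values); adjusted values are
    monotone nondecreasing in the rank of the raw p-value.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    rejected, adjusted, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return rejected, adjusted


def _corr(values: np.ndarray) -> np.ndarray:
    z = values - values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    sd[sd == 0] = np.nan  # zero-variance pseudo-group column: edge dropped to NaN->0 diff
    z = z / sd
    c = (z.T @ z) / (values.shape[0] - 1)
    return np.nan_to_num(c, nan=0.0)


def edgewise_permutation_test(
    table_a: RegionalUptakeTable,
    table_b: RegionalUptakeTable,
    n_perm: int = 10_000,
    seed: int | np.random.Generator | None = None,
    chunk: int = 500,
) -> np.ndarray:
    """Group-label permutation p-values for per-edge correlation differences.

    Two-sided with the add-one correction:
    p = (1 + #{|null dr| >= |observed dr|}) / (n_perm + 1).  The diagonal is
    reported as 1.
    """
    if table_a.region_labels != table_b.region_labels:
        only_a = set(table_a.region_labels) - set(table_b.region_labels)
        only_b = set(table_b.region_labels) - set(table_a.region_labels)
        raise ValueError(
            f"region sets differ (only in A: {sorted(only_a)}, only in B: "
            f"{sorted(only_b)}) or are ordered differently"
        )
    # canonical order: the two-sided statistic |dr| is symmetric in (A, B),
    # so fix the pooling order to make p-values invariant under swapping
    key = lambda t: (t.group_id, t.n_animals)  # noqa: E731
    if key(table_b) < key(table_a):
        table_a, table_b = table_b, table_a
    rng = np.random.default_rng(seed)
    na, nb = table_a.n_animals, table_b.n_animals
    pooled = np.vstack([table_a.values, table_b.values])
    p_regions = pooled.shape[1]
    observed = _corr(table_a.values) - _corr(table_b.values)
    np.fill_diagonal(observed, 0.0)

    exceed = np.zeros((p_regions, p_regions), dtype=np.int64)
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        idx = np.argsort(rng.random((m, na + nb)), axis=1)
        xa = pooled[idx[:, :na]]
        xb = pooled[idx[:, na:]]
        for group, nn in ((xa, na), (xb, nb)):
            mu = group.mean(axis=1, keepdims=True)
            sd = group.std(axis=1, ddof=1, keepdims=True)
            np.divide(group - mu, sd, out=group, where=sd > 0)
        ca = np.einsum("mij,mik->mjk", xa, xa) / (na - 1)
        cb = np.einsum("mij,mik->mjk", xb, xb) / (nb - 1)
        exceed += (np.abs(ca - cb) >= np.abs(observed)[None]).sum(axis=0)
        done += m

    pvals = (1.0 + exceed) / (n_perm + 1.0)
    np.fill_diagonal(pvals, 1.0)
    return pvals


@dataclass(frozen=True)
class ComparisonResult:
    """Between-group comparison of two covariance networks."""

    pair: tuple[str, str]
    ks_stat: float
    ks_p: float
    nodal_ks: dict = field(default_factory=dict)  # metric -> (D, p), per threshold level
    edge_p: np.ndarray | None = field(default=None, repr=False)
    edge_q: np.ndarray | None = field(default=None, repr=False)
    significant_uncorrected: np.ndarray | None = field(default=None, repr=False)
    significant_fdr: np.ndarray | None = field(default=None, repr=False)
    region_labels: tuple[str, ...] = ()

    @property
    def n_significant_uncorrected(self) -> int:
        iu = np.triu_indices(len(self.region_labels), k=1)
        return int(self.significant_uncorrected[iu].sum())

    @property
    def n_significant_fdr(self) -> int:
        iu = np.triu_indices(len(self.region_labels), k=1)
        return int(self.significant_fdr[iu].sum())


def compare_groups(
    table_a: RegionalUptakeTable,
    table_b: RegionalUptakeTable,
    n_perm: int = 10_000,
    fdr_q: float = 0.05,
    uncorrected_level: float = 0.05,
    levels=(0.05, 0.01),
    seed: int | np.random.Generator | None = None,
    networks: tuple[CovarianceNetwork, CovarianceNetwork] | None = None,
    edge_sig_perm: int | None = None,
) -> ComparisonResult:
    """Full pairwise comparison of two groups.

    KS test on the 351 edge weights of the two (unthresholded) networks and
    on the nodal-metric distributions of the thresholded networks at each
    level; edgewise group-label permutation test with BH-FDR adjustment
    over the unique edges.
    """
    rng = np.random.default_rng(seed)
    net_a = networks[0] if networks else covariance_network(table_a)
    net_b = networks[1] if networks else covariance_network(table_b)
    ks_stat, ks_p = ks_two_sample(net_a.edge_values(), net_b.edge_values())

    nodal_ks: dict = {}
    n_sig = edge_sig_perm if edge_sig_perm is not None else n_perm
    if net_a.edge_p is None:
        net_a = net_a.with_edge_p(edge_significance(table_a, n_perm=n_sig, seed=rng))
    if net_b.edge_p is None:
        net_b = net_b.with_edge_p(edge_significance(table_b, n_perm=n_sig, seed=rng))

    for level in levels:
        ma = nodal_metrics(threshold_network(net_a, level))
        mb = nodal_metrics(threshold_network(net_b, level))
        for name in ("degree", "strength_pos", "strength_neg", "clustering"):
            nodal_ks[(name, level)] = ks_two_sample(
                getattr(ma, name).astype(float), getattr(mb, name).astype(float)
            )

    edge_p = edgewise_permutation_test(table_a, table_b, n_perm=n_perm, seed=rng)
    iu = np.triu_indices(len(table_a.region_labels), k=1)
    rejected, adjusted = fdr_bh(edge_p[iu], q=fdr_q)
    edge_q = np.ones_like(edge_p)
    edge_q[iu] = adjusted
    edge_q = np.minimum(edge_q, edge_q.T)
    sig_unc = np.zeros_like(edge_p, dtype=bool)
    sig_unc[iu] = edge_p[iu] < uncorrected_level
    sig_unc |= sig_unc.T
    sig_fdr = np.zeros_like(edge_p, dtype=bool)
    sig_fdr[iu] = rejected
    sig_fdr |= sig_fdr.T

    return ComparisonResult(
        pair=(table_a.group_id, table_b.group_id),
        ks_stat=ks_stat,
        ks_p=ks_p,
        nodal_ks=nodal_ks,
        edge_p=edge_p,
        edge_q=edge_q,
        significant_uncorrected=sig_unc,
        significant_fdr=sig_fdr,
        region_labels=table_a.region_labels,
    )
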