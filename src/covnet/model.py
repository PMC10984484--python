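"""Model/Results interface to the per-group covariance analysis.

`MetabolicCovariance` is built from one group's SUVR table; `fit()` runs
network estimation (Pearson network, random-shift edge significance,
thresholding) and returns a `MetabolicCovarianceResults` object carrying
the estimates and diagnostics, with community detection and a text
`summary()` hanging off it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .community import ConsensusResult, Partition, louvain_signed, mrcc
from .data import RegionalUptakeTable
from .metrics import NodalMetrics, density, hubs, nodal_metrics
from .networks import (
    CovarianceNetwork,
    ThresholdedNetwork,
    covariance_network,
    edge_significance,
    threshold_network,
)


class MetabolicCovariance:
    """Inter-subject metabolic covariance model for one animal group.

    Parameters
    ----------
    table : RegionalUptakeTable
        Animals x regions SUVR table of a homogeneous group.

    Examples
    --------
    >>> from covnet.simulate import GroupSimSpec, generate_group
    >>> spec = GroupSimSpec(n_animals=12, planted_partition=[1]*9 + [2]*9 + [3]*9,
    ...                     rho_within=0.8, seed=7)
    >>> res = MetabolicCovariance(generate_group(spec)).fit(n_perm=2000, seed=1)
    >>> res.network.weights.shape
    (27, 27)
    """

    def __init__(self, table: RegionalUptakeTable):
        self.table = table

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, *, group_id: str, genotype: str, sex: str, age_months: int
    ) -> "MetabolicCovariance":
        return cls(
            RegionalUptakeTable.from_dataframe(
                df, group_id=group_id, genotype=genotype, sex=sex, age_months=age_months
            )
        )

    def fit(
        self,
        levels=(0.05, 0.01),
        n_perm: int = 10_000,
        seed: int | np.random.Generator | None = None,
    ) -> "MetabolicCovarianceResults":
        """Estimate the network, edge p-values and thresholded variants."""
        net = covariance_network(self.table)
        net = net.with_edge_p(edge_significance(self.table, n_perm=n_perm, seed=seed))
        thresholded = {level: threshold_network(net, level) for level in levels}
        return MetabolicCovarianceResults(self, net, thresholded, n_perm=n_perm)


class MetabolicCovarianceResults:
    """Fitted covariance network of one group, with derived measures."""

    def __init__(
        self,
        model: MetabolicCovariance,
        network: CovarianceNetwork,
        thresholded: dict[float, ThresholdedNetwork],
        n_perm: int,
    ):
        self.model = model
        self.network = network
        self.thresholded = thresholded
        self.n_perm = n_perm
        self._consensus: ConsensusResult | None = None

    # -- derived measures ---------------------------------------------------

    def _net_at(self, level: float | None):
        if level is None:
            return self.network
        return self.thresholded[level]

    def density(self, level: float | None = 0.05) -> tuple[int, float]:
        return density(self._net_at(level))

    def nodal_metrics(self, level: float | None = 0.05) -> NodalMetrics:
        return nodal_metrics(self._net_at(level))

    def hubs(self, mode: str = "degree", level: float | None = 0.05,
             quantile: float = 0.25) -> np.ndarray:
        """Hub regions; degree-based hubs require a thresholded network."""
        if mode == "degree" and level is None:
            raise ValueError("degree-based hubs are defined on thresholded networks")
        return hubs(self._net_at(level), mode=mode, quantile=quantile)

    def partition(self, gamma: float = 1.0,
                  seed: int | np.random.Generator | None = None) -> Partition:
        """Single-resolution signed-Louvain partition (unthresholded net)."""
        return louvain_signed(self.network, gamma=gamma, seed=seed)

    def fit_communities(
        self,
        n_partitions: int = 10_000,
        alpha: float = 0.05,
        seed: int | np.random.Generator | None = None,
        **kwargs,
    ) -> ConsensusResult:
        """Multiresolution consensus community structure (cached)."""
        self._consensus = mrcc(
            self.network, n_partitions=n_partitions, alpha=alpha, seed=seed, **kwargs
        )
        return self._consensus

    @property
    def consensus(self) -> ConsensusResult | None:
        return self._consensus

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        t = self.model.table
        lines = [
            "Metabolic covariance network",
            "=" * 60,
            f"group:    {t.group_id} (genotype={t.genotype}, sex={t.sex}, "
            f"age={t.age_months} mo)",
            f"animals:  {t.n_animals}    regions: {t.n_regions}    "
            f"unique edges: {self.network.n_edges}",
            f"edge significance: random-shift null, {self.n_perm} permutations",
            "-" * 60,
            f"{'threshold':<12}{'edges':>8}{'density':>10}{'fragmented':>12}",
        ]
        for level, tn in sorted(self.thresholded.items(), reverse=True):
            cnt, frac = density(tn)
            lines.append(f"p < {level:<8g}{cnt:>8d}{frac:>10.3f}{str(tn.fragmented):>12}")
        m = self.nodal_metrics(level=None)
        lines += [
            "-" * 60,
            f"mean |r|: {np.abs(self.network.edge_values()).mean():.3f}    "
            f"mean clustering (unthresholded): {m.clustering.mean():.3f}",
        ]
        if self._consensus is not None:
            c = self._consensus
            lines += [
                f"consensus communities: {c.consensus.n_communities} "
                f"(ensemble {c.ensemble_size}, alpha {c.alpha}, "
                f"gamma in [{c.gamma_range[0]:.3g}, {c.gamma_range[1]:.3g}])",
            ]
        return "\n".join(lines)
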