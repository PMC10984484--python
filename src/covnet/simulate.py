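"""Synthetic SUVR cohorts with planted modular covariance structure.

The generator draws each animal's 27 regional SUVR values from a
multivariate normal whose correlation matrix is an equicorrelated block
model: region pairs inside the same planted module share ``rho_within``,
pairs in different modules share ``rho_between``.  This is the minimal
model with exactly the structure the pipeline estimates (inter-subject
regional correlation), so every downstream stage has an analytic truth.

Between-module correlation is induced by a shared global factor

    x = sqrt(rho_between) * g + sqrt(rho_within - rho_between) * f_module
        + sqrt(1 - rho_within) * eps

which guarantees a positive-semidefinite correlation matrix whenever
0 <= rho_between <= rho_within < 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .data import (
    AGES_MONTHS,
    N_REGIONS,
    RegionalUptakeTable,
    default_region_labels,
)

#: Published group sizes for the 12-cell (genotype x sex x age) design,
#: keyed by (genotype, sex, age_months).
STUDY_GROUP_SIZES: dict[tuple[str, str, int], int] = {
    ("WT", "M", 4): 12, ("WT", "M", 6): 11, ("WT", "M", 12): 9,
    ("WT", "F", 4): 12, ("WT", "F", 6): 11, ("WT", "F", 12): 10,
    ("5XFAD", "M", 4): 11, ("5XFAD", "M", 6): 10, ("5XFAD", "M", 12): 9,
    ("5XFAD", "F", 4): 12, ("5XFAD", "F", 6): 12, ("5XFAD", "F", 12): 10,
}


def planted_partition_labels(n_regions: int, n_modules: int) -> np.ndarray:
    """Contiguous 1-based module labels splitting regions into near-equal blocks."""
    if not 1 <= n_modules <= n_regions:
        raise ValueError("n_modules must be between 1 and n_regions")
    chunks = np.array_split(np.arange(n_regions), n_modules)
    return np.concatenate([np.full(len(chunk), k + 1) for k, chunk in enumerate(chunks)])


@dataclass(frozen=True)
class GroupSimSpec:
    """Parameters for one simulated group.

    Parameters
    ----------
    n_animals : int
        Animals in the group (>= 3).
    planted_partition : sequence of int
        Module label per region (1-based); its length sets ``n_regions``.
    rho_within : float
        Correlation of region pairs inside a module, in [0, 1).
    rho_between : float
        Correlation across modules, in [0, rho_within].
    mean_suvr : float or array
        Per-region baseline SUVR (default 1.0, the natural scale for a
        cerebellum-referenced ratio).
    mean_shift : float or array
        Additive group effect on the mean (default 0).
    noise_sd : float
        Marginal SUVR standard deviation (default 0.1).
    seed : int
        Seed for the group's own generator.
    """

    n_animals: int
    planted_partition: tuple[int, ...]
    rho_within: float = 0.0
    rho_between: float = 0.0
    mean_suvr: float | tuple[float, ...] = 1.0
    mean_shift: float | tuple[float, ...] = 0.0
    noise_sd: float = 0.1
    seed: int = 0
    group_id: str = "sim"
    genotype: str = "WT"
    sex: str = "M"
    age_months: int = 4
    region_labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        object.__setattr__(self, "planted_partition", tuple(int(m) for m in self.planted_partition))
        if not self.region_labels:
            object.__setattr__(
                self, "region_labels", tuple(default_region_labels(self.n_regions))
            )
        if len(self.region_labels) != self.n_regions:
            raise ValueError("region_labels length must match planted_partition length")
        if not 0.0 <= self.rho_within < 1.0:
            raise ValueError("rho_within must be in [0, 1)")
        if not 0.0 <= self.rho_between <= self.rho_within:
            raise ValueError(
                "rho_between must be in [0, rho_within]; a between-module correlation "
                "above the within-module one has no positive-semidefinite block model "
                "of this form — lower rho_between"
            )
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_animals < 3:
            raise ValueError("n_animals must be >= 3")
        mean = np.broadcast_to(np.asarray(self.mean_suvr, dtype=float), (self.n_regions,))
        if np.any(mean <= 0):
            raise ValueError("mean_suvr must be positive")

    @property
    def n_regions(self) -> int:
        return len(self.planted_partition)

    @property
    def n_modules(self) -> int:
        return len(set(self.planted_partition))


def implied_correlation(spec: GroupSimSpec) -> np.ndarray:
    """Analytic region x region correlation matrix implied by a spec.

    Entry (i, j) is 1 on the diagonal, ``rho_within`` for same-module pairs
    and ``rho_between`` otherwise.  Positive semidefiniteness is guaranteed
    by the shared-factor construction (checked in the spec's validation).
    """
    modules = np.asarray(spec.planted_partition)
    same = modules[:, None] == modules[None, :]
    corr = np.where(same, spec.rho_within, spec.rho_between)
    np.fill_diagonal(corr, 1.0)
    return corr


def generate_group(spec: GroupSimSpec) -> RegionalUptakeTable:
    """Draw one group's SUVR table.

    Rows are i.i.d. multivariate-normal draws with mean
    ``mean_suvr + mean_shift`` and covariance
    ``noise_sd**2 * implied_correlation(spec)``, clipped below at 0.01 so
    SUVR stays strictly positive (the clip probability is negligible at the
    default mean 1.0 / sd 0.1).  The same seed always yields the same table.
    """
    rng = np.random.default_rng(spec.seed)
    modules = np.asarray(spec.planted_partition)
    p = spec.n_regions
    n = spec.n_animals
    module_ids = np.unique(modules)

    g = rng.standard_normal((n, 1))
    f = rng.standard_normal((n, len(module_ids)))
    eps = rng.standard_normal((n, p))
    f_per_region = f[:, np.searchsorted(module_ids, modules)]

    z = (
        np.sqrt(spec.rho_between) * g
        + np.sqrt(spec.rho_within - spec.rho_between) * f_per_region
        + np.sqrt(1.0 - spec.rho_within) * eps
    )
    mean = np.broadcast_to(np.asarray(spec.mean_suvr, dtype=float), (p,)) + np.broadcast_to(
        np.asarray(spec.mean_shift, dtype=float), (p,)
    )
    values = np.clip(mean[None, :] + spec.noise_sd * z, 0.01, None)
    animal_ids = tuple(f"{spec.group_id}_a{i + 1:02d}" for i in range(n))
    return RegionalUptakeTable(
        group_id=spec.group_id,
        genotype=spec.genotype,
        sex=spec.sex,
        age_months=spec.age_months,
        animal_ids=animal_ids,
        region_labels=spec.region_labels,
        values=values,
    )


# Default cohort conditions.  WT groups carry a coarse 3-module covariance
# structure; 5XFAD groups carry a finer 5-module structure (more, smaller
# communities — a less coherent covariance organisation).  Module 1 carries
# an age effect (4 and 12 months elevated relative to 6 months) plus a small
# age-by-sex modulation, so the downstream module-mean ANOVA has a planted
# main effect of age and an age x sex interaction to detect.
DEFAULT_RHO_WITHIN = 0.6
DEFAULT_RHO_BETWEEN = 0.2
DEFAULT_NOISE_SD = 0.1
DEFAULT_N_MODULES = {"WT": 3, "5XFAD": 5}
#: Additive shift applied to module-1 regions, by age in months.
DEFAULT_AGE_SHIFT = {4: 0.05, 6: 0.0, 12: 0.05}
#: Extra module-1 shift in females at 12 months (age x sex interaction).
DEFAULT_AGE_SEX_SHIFT = 0.03


def default_cohort_specs(
    seed: int = 0,
    *,
    group_sizes: Mapping[tuple[str, str, int], int] | None = None,
    rho_within: float = DEFAULT_RHO_WITHIN,
    rho_between: float = DEFAULT_RHO_BETWEEN,
    noise_sd: float = DEFAULT_NOISE_SD,
    age_shift: Mapping[int, float] | None = None,
    age_sex_shift: float = DEFAULT_AGE_SEX_SHIFT,
    n_modules: Mapping[str, int] | None = None,
    n_regions: int = N_REGIONS,
) -> list[GroupSimSpec]:
    """Specs for the full 12-cell (genotype x sex x age) cohort.

    Group sizes default to the published design; per-group seeds are spawned
    deterministically from ``seed``.
    """
    group_sizes = dict(group_sizes or STUDY_GROUP_SIZES)
    age_shift = dict(DEFAULT_AGE_SHIFT if age_shift is None else age_shift)
    n_modules = dict(DEFAULT_N_MODULES if n_modules is None else n_modules)
    region_labels = tuple(default_region_labels(n_regions))
    child_seeds = np.random.SeedSequence(seed).generate_state(len(group_sizes)) % (2**31)

    specs = []
    for k, ((genotype, sex, age), n) in enumerate(sorted(group_sizes.items())):
        modules = planted_partition_labels(n_regions, n_modules[genotype])
        shift = np.zeros(n_regions)
        shift[modules == 1] = age_shift.get(age, 0.0)
        if sex == "F" and age == 12:
            shift[modules == 1] += age_sex_shift
        specs.append(
            GroupSimSpec(
                n_animals=n,
                planted_partition=tuple(modules),
                rho_within=rho_within,
                rho_between=rho_between,
                mean_suvr=1.0,
                mean_shift=tuple(shift),
                noise_sd=noise_sd,
                seed=int(child_seeds[k]),
                group_id=f"{genotype}_{sex}_{age}mo",
                genotype=genotype,
                sex=sex,
                age_months=age,
                region_labels=region_labels,
            )
        )
    return specs


def generate_cohort(
    specs: Sequence[GroupSimSpec] | None = None, *, seed: int = 0, **kwargs
) -> list[RegionalUptakeTable]:
    """Generate the full cohort (12 tables under the default design).

    Either pass explicit ``specs`` or let :func:`default_cohort_specs` build
    them from ``seed`` and keyword overrides.
    """
    if specs is None:
        specs = default_cohort_specs(seed, **kwargs)
    elif kwargs:
        raise TypeError("pass either explicit specs or keyword overrides, not both")
    return [generate_group(spec) for spec in specs]


def null_cohort_specs(seed: int = 0, **kwargs) -> list[GroupSimSpec]:
    """Cohort specs with all group effects removed (exchangeable groups)."""
    kwargs.setdefault("age_shift", {4: 0.0, 6: 0.0, 12: 0.0})
    kwargs.setdefault("age_sex_shift", 0.0)
    kwargs.setdefault("n_modules", {"WT": 3, "5XFAD": 3})
    return default_cohort_specs(seed, **kwargs)
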