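"""Module-mean SUVR extraction and factorial ANOVA with post hoc tests.

Module-average SUVR values are extracted from every group using a single
reference partition (so the same regions are averaged for all groups) and
analysed with an n-way ANOVA with age, sex and genotype as factors,
including all three two-way interactions.  Significant factors are
followed up with Tukey-Kramer pairwise comparisons using the full-model
residual as the error term.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy.stats import studentized_range

from .community import Partition
from .data import RegionalUptakeTable

FACTORS = ("age", "sex", "genotype")
_MODEL_FORMULA = (
    "value ~ C(age) + C(sex) + C(genotype) "
    "+ C(age):C(sex) + C(age):C(genotype) + C(sex):C(genotype)"
)


def module_mean_suvr(
    tables: Sequence[RegionalUptakeTable],
    reference: Partition,
    module_id: int,
) -> pd.DataFrame:
    """Per-animal mean SUVR over the regions of one reference module.

    Returns a long-format frame with columns ``animal, group, genotype,
    sex, age, value`` — one row per animal across all groups, all averaged
    over the *same* region set (the reference partition's module).
    """
    if module_id not in set(int(l) for l in reference.labels):
        raise ValueError(
            f"module {module_id} not present in reference partition "
            f"(communities 1..{reference.n_communities})"
        )
    member_regions = reference.members(module_id)
    rows = []
    for table in tables:
        missing = [r for r in member_regions if r not in table.region_labels]
        if missing:
            raise ValueError(
                f"group {table.group_id!r} lacks reference regions {missing}"
            )
        cols = [table.region_labels.index(r) for r in member_regions]
        means = table.values[:, cols].mean(axis=1)
        for animal, value in zip(table.animal_ids, means):
            rows.append(
                {
                    "animal": animal,
                    "group": table.group_id,
                    "genotype": table.genotype,
                    "sex": table.sex,
                    "age": int(table.age_months),
                    "value": float(value),
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class AnovaResult:
    """Factorial ANOVA table plus what is needed for post hoc tests."""

    table: pd.DataFrame = field(repr=False)  # term -> sum_sq, df, F, PR(>F)
    residual_df: float
    residual_mse: float
    data: pd.DataFrame = field(repr=False)
    ss_type: int = 2

    def f_value(self, term: str) -> float:
        return float(self.table.loc[term, "F"])

    def p_value(self, term: str) -> float:
        return float(self.table.loc[term, "PR(>F)"])

    @property
    def terms(self) -> list[str]:
        return [t for t in self.table.index if t != "Residual"]

    def summary(self) -> str:
        lines = [f"n-way ANOVA (Type {'III' if self.ss_type == 3 else 'II'} SS)"]
        lines.append(
            f"{'term':<24}{'sum_sq':>12}{'df':>6}{'F':>10}{'p':>12}"
        )
        for term in self.terms:
            row = self.table.loc[term]
            lines.append(
                f"{term:<24}{row['sum_sq']:>12.5g}{row['df']:>6.0f}"
                f"{row['F']:>10.3f}{row['PR(>F)']:>12.4g}"
            )
        res = self.table.loc["Residual"]
        lines.append(
            f"{'Residual':<24}{res['sum_sq']:>12.5g}{res['df']:>6.0f}"
        )
        return "\n".join(lines)


def nway_anova(data: pd.DataFrame, ss_type: int = 2) -> AnovaResult:
    """Three-factor ANOVA of module-mean SUVR.

    ``data`` is the long-format frame from :func:`module_mean_suvr`.  The
    model has main effects of age, sex and genotype plus all three two-way
    interactions (no three-way term).  Type II sums of squares by default
    (order-invariant for main effects with mildly unbalanced cells); Type
    III available via ``ss_type=3``.
    """
    for factor in FACTORS:
        if data[factor].nunique() < 2:
            raise ValueError(f"factor {factor!r} needs at least 2 levels")
    cells = data.groupby(["age", "sex", "genotype"], observed=True).size()
    expected = list(
        itertools.product(
            sorted(data["age"].unique()),
            sorted(data["sex"].unique()),
            sorted(data["genotype"].unique()),
        )
    )
    empty = [c for c in expected if c not in cells.index]
    if empty:
        raise ValueError(f"empty design cell(s): {empty}")
    model = smf.ols(_MODEL_FORMULA, data=data).fit()
    table = sm.stats.anova_lm(model, typ=ss_type)
    if "df" not in table.columns:  # anova_lm's column order differs by type
        table = table.rename(columns={"df_resid": "df"})
    readable = {
        "C(age)": "age",
        "C(sex)": "sex",
        "C(genotype)": "genotype",
        "C(age):C(sex)": "age:sex",
        "C(age):C(genotype)": "age:genotype",
        "C(sex):C(genotype)": "sex:genotype",
    }
    table = table.rename(index=readable)
    if "Intercept" in table.index:
        table = table.drop(index="Intercept")
    resid = table.loc["Residual"]
    return AnovaResult(
        table=table,
        residual_df=float(resid["df"]),
        residual_mse=float(resid["sum_sq"] / resid["df"]),
        data=data,
        ss_type=ss_type,
    )


def tukey_kramer(anova: AnovaResult, factor: str) -> pd.DataFrame:
    """Tukey-Kramer pairwise comparisons for one factor.

    Adjusted p-values use the studentized range with the unequal-n (Kramer)
    standard error and the full-model residual mean square and degrees of
    freedom as the error term.
    """
    if factor not in FACTORS:
        raise ValueError(f"factor must be one of {FACTORS}")
    data = anova.data
    levels = sorted(data[factor].unique(), key=str)
    if len(levels) < 2:
        raise ValueError(f"factor {factor!r} has a single level")
    k = len(levels)
    stats_by_level = data.groupby(factor, observed=True)["value"].agg(["mean", "size"])
    rows = []
    for a, b in itertools.combinations(levels, 2):
        ma, na = stats_by_level.loc[a, "mean"], stats_by_level.loc[a, "size"]
        mb, nb = stats_by_level.loc[b, "mean"], stats_by_level.loc[b, "size"]
        se = np.sqrt(anova.residual_mse / 2.0 * (1.0 / na + 1.0 / nb))
        q_obs = abs(ma - mb) / se
        p_adj = float(studentized_range.sf(q_obs, k, anova.residual_df))
        rows.append(
            {
                "level_a": a,
                "level_b": b,
                "diff": float(ma - mb),
                "q": float(q_obs),
                "p_adj": min(1.0, p_adj),
            }
        )
    return pd.DataFrame(rows)
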