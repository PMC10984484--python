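import numpy as np
import pandas as pd
import pytest
from scipy import stats

from covnet.community import Partition
from covnet.data import default_region_labels
from covnet.modstats import module_mean_suvr, nway_anova, tukey_kramer
from covnet.simulate import generate_cohort, null_cohort_specs, planted_partition_labels

REGIONS = tuple(default_region_labels(27))
REFERENCE = Partition(REGIONS, planted_partition_labels(27, 3))


@pytest.fixture(scope="module")
def cohort():
    return generate_cohort(seed=21)


class TestModuleMeanSuvr:
    def test_row_per_animal_with_factors(self, cohort):
        data = module_mean_suvr(cohort, REFERENCE, 1)
        assert len(data) == sum(t.n_animals for t in cohort)
        assert set(data.columns) >= {"animal", "genotype", "sex", "age", "value"}

    def test_single_region_module_returns_that_region(self, cohort):
        single = Partition(REGIONS, [1] + [2] * 26)
        data = module_mean_suvr(cohort, single, 1)
        expected = np.concatenate([t.values[:, 0] for t in cohort])
        np.testing.assert_allclose(np.sort(data["value"]), np.sort(expected))

    def test_constant_table_constant_mean(self, cohort):
        t = cohort[0].with_values(np.full_like(cohort[0].values, 1.3))
        data = module_mean_suvr([t], REFERENCE, 2)
        np.testing.assert_allclose(data["value"], 1.3)

    def test_unknown_module_rejected(self, cohort):
        with pytest.raises(ValueError, match="module 9"):
            module_mean_suvr(cohort, REFERENCE, 9)


class TestNwayAnova:
    def test_balanced_design_reduces_to_classical_sums_of_squares(self):
        # oracle: in a balanced design Type II SS for a main effect equals
        # the classical marginal-means formula sum_l N_l (mean_l - grand)^2
        rng = np.random.default_rng(0)
        rows = []
        for genotype in ("WT", "5XFAD"):
            for sex in ("M", "F"):
                for age in (4, 6, 12):
                    for _ in range(5):
                        rows.append({
                            "genotype": genotype, "sex": sex, "age": age,
                            "value": rng.normal(1.0 + 0.1 * (genotype == "WT"), 0.1),
                        })
        data = pd.DataFrame(rows)
        a = nway_anova(data)
        grand = data["value"].mean()
        for factor in ("genotype", "sex", "age"):
            ss_classical = sum(
                len(sub) * (sub["value"].mean() - grand) ** 2
                for _, sub in data.groupby(factor)
            )
            assert a.table.loc[factor, "sum_sq"] == pytest.approx(ss_classical, rel=1e-10)
        # 10 model parameters: intercept + 2 + 1 + 1 + 2 + 2 + 1
        assert a.table.loc["Residual", "df"] == len(data) - 10

    def test_planted_age_effect_detected(self):
        tables = generate_cohort(seed=3)
        a = nway_anova(module_mean_suvr(tables, REFERENCE, 1))
        assert a.p_value("age") < 0.05
        assert set(a.terms) == {
            "age", "sex", "genotype", "age:sex", "age:genotype", "sex:genotype"
        }

    def test_null_cohort_module2_not_systematically_significant(self):
        tables = generate_cohort(null_cohort_specs(17))
        a = nway_anova(module_mean_suvr(tables, REFERENCE, 2))
        assert a.p_value("age") > 0.001  # no planted effect on module 2

    def test_balanced_design_order_invariant(self):
        rng = np.random.default_rng(1)
        rows = []
        for genotype in ("WT", "5XFAD"):
            for sex in ("M", "F"):
                for age in (4, 6, 12):
                    for _ in range(4):
                        rows.append({"genotype": genotype, "sex": sex, "age": age,
                                     "value": rng.normal(1, 0.1)})
        data = pd.DataFrame(rows)
        a1 = nway_anova(data)
        a2 = nway_anova(data.sample(frac=1.0, random_state=0))
        for term in a1.terms:
            assert a1.f_value(term) == pytest.approx(a2.f_value(term), rel=1e-10)

    def test_single_level_factor_rejected(self):
        data = pd.DataFrame({
            "genotype": ["WT"] * 12,
            "sex": ["M", "F"] * 6,
            "age": [4, 6, 12] * 4,
            "value": np.random.default_rng(0).normal(1, 0.1, 12),
        })
        with pytest.raises(ValueError, match="genotype"):
            nway_anova(data)

    def test_empty_cell_listed(self):
        rng = np.random.default_rng(2)
        rows = []
        for genotype in ("WT", "5XFAD"):
            for sex in ("M", "F"):
                for age in (4, 6, 12):
                    if genotype == "5XFAD" and sex == "F" and age == 12:
                        continue
                    for _ in range(3):
                        rows.append({"genotype": genotype, "sex": sex, "age": age,
                                     "value": rng.normal(1, 0.1)})
        with pytest.raises(ValueError, match="empty design cell"):
            nway_anova(pd.DataFrame(rows))


class TestTukeyKramer:
    @pytest.fixture(scope="class")
    def fitted(self):
        tables = generate_cohort(seed=5)
        return nway_anova(module_mean_suvr(tables, REFERENCE, 1))

    def test_family_size(self, fitted):
        posthoc = tukey_kramer(fitted, "age")
        assert len(posthoc) == 3  # k(k-1)/2 for k = 3 ages

    def test_equal_means_p_near_one(self):
        rng = np.random.default_rng(3)
        rows = []
        for genotype in ("WT", "5XFAD"):
            for sex in ("M", "F"):
                for age in (4, 6, 12):
                    for _ in range(6):
                        rows.append({"genotype": genotype, "sex": sex, "age": age,
                                     "value": 1.0})
        data = pd.DataFrame(rows)
        data["value"] += rng.normal(0, 1e-9, len(data))
        a = nway_anova(data)
        posthoc = tukey_kramer(a, "sex")
        assert posthoc["p_adj"].iloc[0] > 0.5

    def test_adjusted_at_least_pairwise_t(self, fitted):
        # conservativeness vs the pairwise t-test with the same error term
        posthoc = tukey_kramer(fitted, "age")
        data = fitted.data
        for _, row in posthoc.iterrows():
            nx = (data.age == row.level_a).sum()
            ny = (data.age == row.level_b).sum()
            se = np.sqrt(fitted.residual_mse * (1 / nx + 1 / ny))
            t = abs(row["diff"]) / se
            p_t = 2 * stats.t.sf(t, fitted.residual_df)
            assert row.p_adj >= p_t - 1e-12

    def test_planted_age_pattern(self, fitted):
        # ages 4 and 12 are shifted relative to 6; the 4-12 pair is not
        posthoc = tukey_kramer(fitted, "age").set_index(["level_a", "level_b"])
        assert posthoc.loc[(4, 6), "p_adj"] < 0.05 or posthoc.loc[(12, 6), "p_adj"] < 0.05

    def test_unknown_factor_rejected(self, fitted):
        with pytest.raises(ValueError, match="factor"):
            tukey_kramer(fitted, "weight")
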