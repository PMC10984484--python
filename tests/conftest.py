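import numpy as np
import pytest

from covnet.data import RegionalUptakeTable, default_region_labels
from covnet.simulate import GroupSimSpec, generate_group

PLANTED_3 = tuple([1] * 9 + [2] * 9 + [3] * 9)


@pytest.fixture(scope="session")
def planted_partition():
    return PLANTED_3


@pytest.fixture(scope="session")
def modular_table() -> RegionalUptakeTable:
    """12 animals x 27 regions with a strong planted 3-module structure."""
    return generate_group(
        GroupSimSpec(n_animals=12, planted_partition=PLANTED_3, rho_within=0.8, seed=7)
    )


@pytest.fixture(scope="session")
def null_table() -> RegionalUptakeTable:
    """12 animals x 27 regions with no inter-regional correlation."""
    return generate_group(
        GroupSimSpec(n_animals=12, planted_partition=PLANTED_3, rho_within=0.0, seed=11)
    )


@pytest.fixture()
def tiny_table() -> RegionalUptakeTable:
    rng = np.random.default_rng(3)
    return RegionalUptakeTable(
        group_id="tiny",
        genotype="WT",
        sex="F",
        age_months=6,
        animal_ids=tuple(f"a{i}" for i in range(5)),
        region_labels=tuple(default_region_labels(4)),
        values=1.0 + 0.1 * rng.standard_normal((5, 4)),
    )
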