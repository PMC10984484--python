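"""Regional uptake tables and delimited-text I/O.

The atomic input of every analysis stage is a table of standardized uptake
value ratios (SUVR): one row per animal, one column per (bilaterally
averaged) brain region, attached to the group metadata (genotype, sex, age)
that defines a homogeneous imaging cohort.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

GENOTYPES = ("WT", "5XFAD")
SEXES = ("M", "F")
AGES_MONTHS = (4, 6, 12)

#: Number of bilaterally averaged regions carried through the whole analysis.
N_REGIONS = 27


def default_region_labels(n_regions: int = N_REGIONS) -> list[str]:
    """Placeholder region labels (``R01`` ... ``R27``) for simulated cohorts."""
    width = len(str(n_regions))
    return [f"R{i + 1:0{width}d}" for i in range(n_regions)]


@dataclass(frozen=True)
class RegionalUptakeTable:
    """Animals x regions SUVR matrix for one homogeneous group.

    Parameters
    ----------
    group_id : str
        Free-form label for the group (e.g. ``"WT_M_4mo"``).
    genotype : str
        ``"WT"`` or ``"5XFAD"``.
    sex : str
        ``"M"`` or ``"F"``.
    age_months : int
        Age at imaging, one of 4, 6 or 12 months.
    animal_ids : tuple of str
        Unique identifier per animal (row).
    region_labels : tuple of str
        Unique region label per column.
    values : ndarray, shape (n_animals, n_regions)
        SUVR values; finite, strictly positive, no missing entries.
    """

    group_id: str
    genotype: str
    sex: str
    age_months: int
    animal_ids: tuple[str, ...]
    region_labels: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "animal_ids", tuple(str(a) for a in self.animal_ids))
        object.__setattr__(self, "region_labels", tuple(str(r) for r in self.region_labels))
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if self.genotype not in GENOTYPES:
            raise ValueError(f"genotype must be one of {GENOTYPES}, got {self.genotype!r}")
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if int(self.age_months) not in AGES_MONTHS:
            raise ValueError(f"age_months must be one of {AGES_MONTHS}, got {self.age_months!r}")
        if values.ndim != 2:
            raise ValueError("values must be a 2-D (animals x regions) matrix")
        n, p = values.shape
        if n != len(self.animal_ids):
            raise ValueError("number of rows must match number of animal_ids")
        if p != len(self.region_labels):
            raise ValueError("number of columns must match number of region_labels")
        if len(set(self.animal_ids)) != n:
            raise ValueError("animal_ids must be unique")
        if len(set(self.region_labels)) != p:
            raise ValueError("region_labels must be unique")
        if n < 3:
            raise ValueError(
                f"group {self.group_id!r} has n={n} animals; at least 3 are required "
                "for a meaningful inter-subject correlation"
            )
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite SUVR at animal {self.animal_ids[bad[0]]!r}, "
                f"region {self.region_labels[bad[1]]!r}"
            )
        if np.any(values <= 0):
            bad = np.argwhere(values <= 0)[0]
            raise ValueError(
                f"non-positive SUVR at animal {self.animal_ids[bad[0]]!r}, "
                f"region {self.region_labels[bad[1]]!r}"
            )

    @property
    def n_animals(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.animal_ids), columns=list(self.region_labels)
        )

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        *,
        group_id: str,
        genotype: str,
        sex: str,
        age_months: int,
    ) -> "RegionalUptakeTable":
        return cls(
            group_id=group_id,
            genotype=genotype,
            sex=sex,
            age_months=int(age_months),
            animal_ids=tuple(str(i) for i in df.index),
            region_labels=tuple(str(c) for c in df.columns),
            values=df.to_numpy(dtype=float),
        )

    def with_values(self, values: np.ndarray) -> "RegionalUptakeTable":
        """Copy of the table with a replaced value matrix (same shape)."""
        return replace(self, values=np.asarray(values, dtype=float))


def _detect_delimiter(text: str) -> str:
    first = text.splitlines()[0] if text.splitlines() else ""
    return "\t" if first.count("\t") >= first.count(",") and "\t" in first else ","


def read_uptake_table(
    path,
    *,
    group_id: str,
    genotype: str,
    sex: str,
    age_months: int,
) -> RegionalUptakeTable:
    """Read an animals x regions SUVR table from delimited text.

    First row: region labels (first cell is the animal-id column header).
    First column: animal ids. Delimiter is auto-detected (comma or tab).
    Missing cells, duplicate labels and groups of fewer than 3 animals are
    hard errors naming the offending cell/label.
    """
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    sep = _detect_delimiter(text)
    rows = list(csv.reader(io.StringIO(text), delimiter=sep))
    rows = [r for r in rows if r and any(c.strip() for c in r)]
    if len(rows) < 2:
        raise ValueError(f"{path}: expected a header row and at least one data row")
    header = [c.strip() for c in rows[0]]
    region_labels = header[1:]
    if len(set(region_labels)) != len(region_labels):
        dupes = sorted({r for r in region_labels if region_labels.count(r) > 1})
        raise ValueError(f"{path}: duplicate region label(s) {dupes}")
    animal_ids: list[str] = []
    values = np.empty((len(rows) - 1, len(region_labels)), dtype=float)
    for i, row in enumerate(rows[1:]):
        if len(row) != len(header):
            raise ValueError(
                f"{path}: row {i + 2} has {len(row)} cells, expected {len(header)}"
            )
        animal_ids.append(row[0].strip())
        for j, cell in enumerate(row[1:]):
            if cell.strip() == "":
                raise ValueError(
                    f"{path}: empty cell at animal {row[0].strip()!r}, "
                    f"region {region_labels[j]!r}"
                )
            try:
                values[i, j] = float(cell)
            except ValueError as exc:
                raise ValueError(
                    f"{path}: non-numeric cell {cell!r} at animal {row[0].strip()!r}, "
                    f"region {region_labels[j]!r}"
                ) from exc
    return RegionalUptakeTable(
        group_id=group_id,
        genotype=genotype,
        sex=sex,
        age_months=int(age_months),
        animal_ids=tuple(animal_ids),
        region_labels=tuple(region_labels),
        values=values,
    )


def write_uptake_table(table: RegionalUptakeTable, path, *, sep: str = ",") -> None:
    """Write a table in the same dialect :func:`read_uptake_table` reads."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=sep)
        writer.writerow(["animal", *table.region_labels])
        for animal, row in zip(table.animal_ids, table.values):
            writer.writerow([animal, *(f"{v:.17g}" for v in row)])


def write_matrix(matrix: np.ndarray, labels, path, *, sep: str = ",") -> None:
    """Write a labeled square region x region matrix as delimited text.

    Header row and header column carry the region labels; values are written
    with enough digits that a read-back round trip is exact to < 1e-12.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError(f"matrix must be square, got shape {matrix.shape}")
    labels = [str(l) for l in labels]
    if len(labels) != matrix.shape[0]:
        raise ValueError("label count must match matrix size")
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=sep)
        writer.writerow(["region", *labels])
        for label, row in zip(labels, matrix):
            writer.writerow([label, *(f"{v:.17g}" for v in row)])


def read_matrix(path) -> tuple[np.ndarray, list[str]]:
    """Read a labeled square matrix written by :func:`write_matrix`."""
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    labels = [str(c) for c in df.columns]
    if list(map(str, df.index)) != labels:
        raise ValueError(f"{path}: row labels do not match column labels")
    return df.to_numpy(dtype=float), labels


def write_partition(labels_by_region: dict[str, int], path) -> None:
    """Write a two-column (region, community) CSV."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["region", "community"])
        for region, label in labels_by_region.items():
            writer.writerow([region, int(label)])


def read_partition(path) -> dict[str, int]:
    df = pd.read_csv(path)
    return {str(r): int(l) for r, l in zip(df["region"], df["community"])}
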