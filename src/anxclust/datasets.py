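"""Country-level pre-exam anxiety records: validation, CSV I/O, bundled tables.

A dataset is one activity stratum — the percentage of students in each
country reporting pre-exam anxiety, among either low or high physically
active students. Three bundled fixtures transcribe the published
country-by-country tables:

``table1_low``
    56 countries, low-activity stratum, integer percentages, with the
    published five-cluster assignment.
``table2_high``
    the same 56 countries, high-activity stratum, with the published
    four-cluster assignment.
``table3_paired``
    16 rows (15 countries + the OECD average) of paired low/high group
    means with standard errors for the two-group comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .hierarchy import Partition

GROUPS = ("low", "high")
FIXTURES = ("table1_low", "table2_high", "table3_paired")

__all__ = [
    "GROUPS",
    "FIXTURES",
    "CountryRecord",
    "Dataset",
    "ValidationError",
    "load_dataset",
    "write_dataset",
    "bundled_fixture",
    "printed_partition",
]


class ValidationError(ValueError):
    """A record or file violates the dataset schema."""


@dataclass(frozen=True)
class CountryRecord:
    """One country's anxiety percentage within one activity stratum."""

    country: str
    activity_group: str
    anxiety_pct: float
    se: float | None = None

    def __post_init__(self) -> None:
        name = self.country.strip()
        if not name:
            raise ValidationError("country name must be non-empty")
        object.__setattr__(self, "country", name)
        if self.activity_group not in GROUPS:
            raise ValidationError(
                f"activity_group must be one of {GROUPS}, got {self.activity_group!r}"
            )
        pct = float(self.anxiety_pct)
        if not np.isfinite(pct) or not 0.0 <= pct <= 100.0:
            raise ValidationError(
                f"{name}: anxiety_pct must be a percentage in [0, 100], got {self.anxiety_pct!r}"
            )
        object.__setattr__(self, "anxiety_pct", pct)
        if self.se is not None:
            se = float(self.se)
            if not np.isfinite(se) or se <= 0:
                raise ValidationError(f"{name}: se must be positive, got {self.se!r}")
            object.__setattr__(self, "se", se)


@dataclass(frozen=True)
class Dataset:
    """Ordered collection of CountryRecord for one activity stratum.

    Record order is stable and defines the leaf indexing used by the
    clustering downstream.
    """

    group_label: str
    records: tuple[CountryRecord, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        if self.group_label not in GROUPS:
            raise ValidationError(f"group_label must be one of {GROUPS}")
        if len(self.records) < 2:
            raise ValidationError(f"a dataset needs at least 2 records, got {len(self.records)}")
        names = [r.country for r in self.records]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValidationError(f"duplicate countries in {self.group_label} dataset: {sorted(dupes)}")
        wrong = [r.country for r in self.records if r.activity_group != self.group_label]
        if wrong:
            raise ValidationError(f"records not in group {self.group_label!r}: {wrong}")

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def countries(self) -> tuple[str, ...]:
        return tuple(r.country for r in self.records)

    @property
    def values(self) -> np.ndarray:
        return np.array([r.anxiety_pct for r in self.records], dtype=float)

    def record(self, country: str) -> CountryRecord:
        for r in self.records:
            if r.country == country:
                return r
        raise KeyError(country)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"country": r.country, "group": r.activity_group, "anxiety_pct": r.anxiety_pct, "se": r.se}
            for r in self.records
        ]
        df = pd.DataFrame(rows)
        if df["se"].isna().all():
            df = df.drop(columns=["se"])
        return df


def _dataset_from_frame(df: pd.DataFrame, group: str, source: str = "<frame>") -> Dataset:
    required = {"country", "group", "anxiety_pct"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{source}: missing required column(s) {sorted(missing)}")
    sub = df[df["group"] == group]
    records = []
    for idx, row in sub.iterrows():
        pct = pd.to_numeric(pd.Series([row["anxiety_pct"]]), errors="coerce").iloc[0]
        if pd.isna(pct):
            raise ValidationError(f"{source} row {idx}: non-numeric anxiety_pct {row['anxiety_pct']!r}")
        se = row.get("se")
        se = None if se is None or pd.isna(se) else float(se)
        try:
            records.append(CountryRecord(str(row["country"]), group, float(pct), se))
        except ValidationError as exc:
            raise ValidationError(f"{source} row {idx}: {exc}") from exc
    if len(records) < 2:
        raise ValidationError(f"{source}: fewer than 2 rows for group {group!r}")
    return Dataset(group, tuple(records))


def load_dataset(path: str | Path, group: str) -> Dataset:
    """Load one activity stratum from a CSV with columns country,group,anxiety_pct[,se]."""
    if group not in GROUPS:
        raise ValidationError(f"group must be one of {GROUPS}")
    path = Path(path)
    df = pd.read_csv(path)
    return _dataset_from_frame(df, group, source=str(path))


def write_dataset(data: Dataset, path: str | Path) -> None:
    """Write a Dataset back to the CSV interchange schema (UTF-8, comma, header)."""
    data.to_frame().to_csv(path, index=False)


def _fixture_frame(name: str) -> pd.DataFrame:
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {FIXTURES}")
    with resources.files("anxclust.fixtures").joinpath(f"{name}.csv").open("r") as fh:
        return pd.read_csv(fh)


def bundled_fixture(name: str):
    """Return a bundled published table.

    ``table1_low`` / ``table2_high`` -> Dataset (56 countries each);
    ``table3_paired`` -> DataFrame of paired group means and standard errors.
    """
    df = _fixture_frame(name)
    if name == "table3_paired":
        return df
    group = "low" if name == "table1_low" else "high"
    return _dataset_from_frame(df, group, source=name)


def printed_partition(name: str) -> Partition:
    """The published cluster assignment shipped alongside a fixture table."""
    if name == "table3_paired":
        raise KeyError("table3_paired has no single-stratum cluster assignment")
    df = _fixture_frame(name)
    return Partition(dict(zip(df["country"], df["cluster"])))
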