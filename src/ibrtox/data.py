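"""Domain types, long-format table I/O, validation, and group summaries.

The canonical on-disk representation is a tidy (long) table: one row per
measurement of one biomarker in one tissue of one animal at one timepoint.
Wide matrices used by the ordination stage are derived views (see
:mod:`ibrtox.pipeline`).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

TISSUES = ("gills", "hepatopancreas", "muscle")
TREATMENTS = ("CTRL", "C1", "C2", "C3")
#: Nominal exposure concentration of each treatment group, mg/L.
DOSES = {"CTRL": 0.0, "C1": 0.5, "C2": 5.0, "C3": 25.0}
DAYS = (10, 20)
BIOMARKERS = ("SOD", "GPx", "GST", "MDA")
#: Declared unit of each biomarker after protein normalisation.
UNITS = {
    "SOD": "U mg-1 protein",
    "GPx": "nmol (mg*min)-1",
    "GST": "nmol (ug*min)-1",
    "MDA": "umol mg-1 protein",
}
COMPARTMENTS = ("hemolymph", "hepatopancreas")
ASSAYS = ("NR", "TB")

BIOMARKER_COLUMNS = ("subject_id", "tissue", "treatment", "day", "biomarker", "value", "unit")
VIABILITY_COLUMNS = ("subject_id", "compartment", "assay", "treatment", "day", "percent_viable")


class SchemaError(ValueError):
    """A required column is missing or the header is malformed."""


class RowError(ValueError):
    """A data row failed validation; carries the 0-based data-row index."""

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")


@dataclass(frozen=True)
class BiomarkerRecord:
    """One protein-normalised biomarker measurement.

    ``unit`` defaults to the declared unit of ``biomarker``; supplying a
    conflicting unit is an error rather than a silent conversion.
    """

    subject_id: str
    tissue: str
    treatment: str
    day: int
    biomarker: str
    value: float
    unit: str = field(default="")

    def __post_init__(self):
        if self.tissue not in TISSUES:
            raise ValueError(f"unknown tissue {self.tissue!r}")
        if self.treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r}")
        if int(self.day) not in DAYS:
            raise ValueError(f"unknown exposure day {self.day!r}")
        if self.biomarker not in BIOMARKERS:
            raise ValueError(f"unknown biomarker {self.biomarker!r}")
        if not np.isfinite(self.value) or self.value < 0:
            raise ValueError(f"biomarker value must be finite and >= 0, got {self.value!r}")
        expected = UNITS[self.biomarker]
        if self.unit == "":
            object.__setattr__(self, "unit", expected)
        elif self.unit != expected:
            raise ValueError(
                f"unit {self.unit!r} does not match declared unit {expected!r} for {self.biomarker}"
            )

    @property
    def dose(self) -> float:
        """Exposure concentration attached to the treatment label, mg/L."""
        return DOSES[self.treatment]


@dataclass(frozen=True)
class ViabilityRecord:
    """Percent viable cells for one animal, compartment and assay."""

    subject_id: str
    compartment: str
    assay: str
    treatment: str
    day: int
    percent_viable: float

    def __post_init__(self):
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {self.compartment!r}")
        if self.assay not in ASSAYS:
            raise ValueError(f"unknown assay {self.assay!r}")
        if self.treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r}")
        if int(self.day) not in DAYS:
            raise ValueError(f"unknown exposure day {self.day!r}")
        if not (0.0 <= self.percent_viable <= 100.0):
            raise ValueError(f"percent_viable must lie in [0, 100], got {self.percent_viable!r}")


def _read_frame(source, sep: str, decimal: str, columns: Sequence[str]) -> pd.DataFrame:
    if isinstance(source, (str, bytes)) and "\n" in str(source):
        source = io.StringIO(str(source))
    df = pd.read_csv(source, sep=sep, decimal=decimal, dtype=str, keep_default_na=False)
    for col in columns:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r}")
    return df


def read_biomarker_table(source, *, sep: str = ",", decimal: str = ".") -> pd.DataFrame:
    """Read and validate a long-format biomarker table.

    Parameters
    ----------
    source : path, file-like, or CSV text
        Delimited text with the columns ``subject_id, tissue, treatment, day,
        biomarker, value, unit`` (``unit`` may be empty).
    sep, decimal : str
        CSV dialect; defaults are comma separator and "." decimal point.

    Returns
    -------
    pandas.DataFrame
        One validated row per input row, in input order, with a ``dose``
        column (mg/L) attached.

    Raises
    ------
    SchemaError
        If a required column is missing.
    RowError
        For the first unparseable value, unknown factor level, negative
        value, or duplicated (tissue, treatment, day, biomarker, subject)
        key, identified by 0-based data-row index.
    """
    df = _read_frame(source, sep, decimal, BIOMARKER_COLUMNS[:-1])
    if "unit" not in df.columns:
        df["unit"] = ""
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            day = int(row.day)
            value = float(str(row.value).replace(decimal, "."))
        except (TypeError, ValueError) as exc:
            raise RowError(i, f"unparseable value: {exc}") from exc
        try:
            rec = BiomarkerRecord(
                subject_id=str(row.subject_id),
                tissue=str(row.tissue),
                treatment=str(row.treatment),
                day=day,
                biomarker=str(row.biomarker),
                value=value,
                unit=str(row.unit),
            )
        except ValueError as exc:
            raise RowError(i, str(exc)) from exc
        records.append(rec)
    out = records_to_frame(records)
    key = ["tissue", "treatment", "day", "biomarker", "subject_id"]
    dup = out.duplicated(subset=key)
    if dup.any():
        raise RowError(int(np.flatnonzero(dup.to_numpy())[0]), "duplicate measurement key")
    return out


def records_to_frame(records: Iterable[BiomarkerRecord]) -> pd.DataFrame:
    rows = [
        (r.subject_id, r.tissue, r.treatment, r.day, r.biomarker, r.value, r.unit, r.dose)
        for r in records
    ]
    return pd.DataFrame(rows, columns=list(BIOMARKER_COLUMNS) + ["dose"])


def frame_to_records(df: pd.DataFrame) -> list[BiomarkerRecord]:
    return [
        BiomarkerRecord(
            subject_id=str(r.subject_id),
            tissue=r.tissue,
            treatment=r.treatment,
            day=int(r.day),
            biomarker=r.biomarker,
            value=float(r.value),
            unit=getattr(r, "unit", "") or "",
        )
        for r in df.itertuples(index=False)
    ]


def write_biomarker_table(df: pd.DataFrame, target, *, sep: str = ",") -> None:
    """Write a biomarker table; the derived ``dose`` column is not persisted."""
    df[list(BIOMARKER_COLUMNS)].to_csv(target, sep=sep, index=False)


def read_viability_table(source, *, sep: str = ",", decimal: str = ".") -> pd.DataFrame:
    """Read and validate a long-format viability table (see :func:`read_biomarker_table`)."""
    df = _read_frame(source, sep, decimal, VIABILITY_COLUMNS)
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            day = int(row.day)
            pct = float(str(row.percent_viable).replace(decimal, "."))
        except (TypeError, ValueError) as exc:
            raise RowError(i, f"unparseable value: {exc}") from exc
        try:
            rec = ViabilityRecord(
                subject_id=str(row.subject_id),
                compartment=str(row.compartment),
                assay=str(row.assay),
                treatment=str(row.treatment),
                day=day,
                percent_viable=pct,
            )
        except ValueError as exc:
            raise RowError(i, str(exc)) from exc
        records.append(rec)
    rows = [
        (r.subject_id, r.compartment, r.assay, r.treatment, r.day, r.percent_viable)
        for r in records
    ]
    return pd.DataFrame(rows, columns=list(VIABILITY_COLUMNS))


def write_viability_table(df: pd.DataFrame, target, *, sep: str = ",") -> None:
    df[list(VIABILITY_COLUMNS)].to_csv(target, sep=sep, index=False)


def summarize_groups(df: pd.DataFrame) -> pd.DataFrame:
    """Per-cell n, mean and sample SD over (tissue, treatment, day, biomarker).

    The SD uses the n−1 denominator and is NaN (undefined, not 0) for
    singleton cells; downstream stages must handle that case explicitly.
    """
    if len(df) == 0:
        raise ValueError("summarize_groups requires a nonempty table")
    grouped = df.groupby(["tissue", "treatment", "day", "biomarker"], sort=True, observed=True)[
        "value"
    ]
    out = grouped.agg(n="count", mean="mean", sd=lambda v: v.std(ddof=1)).reset_index()
    out.loc[out["n"] == 1, "sd"] = np.nan
    return out
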