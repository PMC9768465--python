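"""Record data model and CSV/JSON I/O.

A *record* is one reported Pearson correlation together with its statistical
context: the coefficient ``r`` (signed when the sign is known), the sample
size ``N`` or degrees of freedom (``df = N - 2``), any reported p-value, the
claimed significance status, and where in the article the value appeared
(running text vs. a correlation table), plus study/journal/year strata.

The CSV schema is fixed: comma-separated, UTF-8, ``.`` decimal, with columns
``record_id, r, n, df, p_comparator, p_value, sig_label, location, study_id,
journal, subfield, year``.  Blank cells mean "not reported".  A column-mapping
option lets :func:`read_records_csv` adapt externally deposited tables whose
headers differ.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Comparator",
    "SigLabel",
    "Location",
    "Sidedness",
    "PValueReport",
    "StatRecord",
    "RejectedRow",
    "RecordSet",
    "AnalysisConfig",
    "SchemaError",
    "read_records_csv",
    "write_records_csv",
    "merge_strata",
]

CSV_COLUMNS = [
    "record_id",
    "r",
    "n",
    "df",
    "p_comparator",
    "p_value",
    "sig_label",
    "location",
    "study_id",
    "journal",
    "subfield",
    "year",
]


class Comparator(Enum):
    """How a p-value was reported: ``p =``, ``p <`` or ``p >``."""

    EQ = "EQ"
    LT = "LT"
    GT = "GT"


class SigLabel(Enum):
    SIGNIFICANT = "SIGNIFICANT"
    NON_SIGNIFICANT = "NON_SIGNIFICANT"
    UNSPECIFIED = "UNSPECIFIED"


class Location(Enum):
    TEXT = "TEXT"
    TABLE = "TABLE"
    UNKNOWN = "UNKNOWN"


class Sidedness(Enum):
    ONE_SIDED = "ONE_SIDED"
    TWO_SIDED = "TWO_SIDED"


class SchemaError(ValueError):
    """The input file does not carry the mandatory columns."""


@dataclass(frozen=True)
class PValueReport:
    """A reported p-value with its comparator (``p = v``, ``p < v``, ``p > v``)."""

    comparator: Comparator
    value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0:
            raise ValueError(f"p-value {self.value} outside [0, 1]")


@dataclass(frozen=True)
class StatRecord:
    """One reported correlation with its statistical context.

    Either ``n`` (total sample size) or ``df`` (degrees of freedom,
    ``df = n - 2``) may be present; :meth:`effective_df` derives the other on
    demand.  ``abs_r`` is always ``|r|``; ``r`` keeps the sign when known.
    """

    record_id: str
    r: float
    n: int | None = None
    df: int | None = None
    p_report: PValueReport | None = None
    sig_label: SigLabel = SigLabel.UNSPECIFIED
    location: Location = Location.UNKNOWN
    study_id: str | None = None
    journal: str | None = None
    subfield: str | None = None
    year: int | None = None

    def __post_init__(self) -> None:
        if not -1.0 <= self.r <= 1.0:
            raise ValueError(f"r={self.r} outside [-1, 1]")
        if self.n is not None and self.n < 3:
            raise ValueError(f"n={self.n} < 3")
        if self.df is not None and self.df < 0:
            raise ValueError(f"df={self.df} < 0")

    @property
    def abs_r(self) -> float:
        return abs(self.r)

    def effective_df(self) -> int | None:
        """df as reported, else n - 2, else None."""
        if self.df is not None:
            return self.df
        if self.n is not None:
            return self.n - 2
        return None

    def n_df_consistent(self) -> bool:
        """False only when both n and df are present and df != n - 2."""
        if self.n is None or self.df is None:
            return True
        return self.df == self.n - 2


@dataclass(frozen=True)
class RejectedRow:
    row_index: int  # 0-based data-row index (header excluded)
    reason: str


@dataclass
class RecordSet:
    """An ordered collection of :class:`StatRecord` with unique ids."""

    records: list[StatRecord] = field(default_factory=list)
    provenance: str = ""
    rejected: list[RejectedRow] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [rec.record_id for rec in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("record_ids are not unique")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[StatRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> StatRecord:
        return self.records[i]

    def abs_r_values(self) -> list[float]:
        return [rec.abs_r for rec in self.records]

    def to_frame(self) -> pd.DataFrame:
        """Records as a DataFrame in the canonical CSV schema (NaN = absent)."""
        rows = []
        for rec in self.records:
            rows.append(
                {
                    "record_id": rec.record_id,
                    "r": rec.r,
                    "n": rec.n,
                    "df": rec.df,
                    "p_comparator": rec.p_report.comparator.value if rec.p_report else None,
                    "p_value": rec.p_report.value if rec.p_report else None,
                    "sig_label": rec.sig_label.value,
                    "location": rec.location.value,
                    "study_id": rec.study_id,
                    "journal": rec.journal,
                    "subfield": rec.subfield,
                    "year": rec.year,
                }
            )
        return pd.DataFrame(rows, columns=CSV_COLUMNS)


@dataclass(frozen=True)
class AnalysisConfig:
    """Shared analysis knobs: significance level, sidedness, bootstrap size, seed."""

    alpha: float = 0.05
    sidedness: Sidedness = Sidedness.TWO_SIDED
    bootstrap_reps: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha={self.alpha} outside (0, 1)")
        if self.bootstrap_reps < 1:
            raise ValueError("bootstrap_reps must be positive")


def _cell(value: object) -> str | None:
    """Normalize a raw CSV cell: strip; empty/NaN -> None."""
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    text = str(value).strip()
    return text or None


def _parse_row(raw: Mapping[str, object], row_index: int) -> StatRecord:
    def get(col: str) -> str | None:
        return _cell(raw.get(col))

    r_cell = get("r")
    if r_cell is None:
        raise ValueError("missing r")
    try:
        r = float(r_cell)
    except ValueError as exc:
        raise ValueError(f"unparseable r cell {r_cell!r}") from exc

    def parse_int(col: str) -> int | None:
        cell = get(col)
        if cell is None:
            return None
        try:
            value = float(cell)
        except ValueError as exc:
            raise ValueError(f"unparseable {col} cell {cell!r}") from exc
        if value != int(value):
            raise ValueError(f"non-integer {col} cell {cell!r}")
        return int(value)

    n = parse_int("n")
    df = parse_int("df")

    p_report = None
    comp_cell, pval_cell = get("p_comparator"), get("p_value")
    if pval_cell is not None:
        comparator = Comparator(comp_cell) if comp_cell else Comparator.EQ
        p_report = PValueReport(comparator, float(pval_cell))

    sig_cell = get("sig_label")
    sig = SigLabel(sig_cell) if sig_cell else SigLabel.UNSPECIFIED
    loc_cell = get("location")
    loc = Location(loc_cell) if loc_cell else Location.UNKNOWN
    year = parse_int("year")

    return StatRecord(
        record_id=get("record_id") or f"row{row_index}",
        r=r,
        n=n,
        df=df,
        p_report=p_report,
        sig_label=sig,
        location=loc,
        study_id=get("study_id"),
        journal=get("journal"),
        subfield=get("subfield"),
        year=year,
    )


def read_records_csv(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> RecordSet:
    """Read a records CSV into a :class:`RecordSet`.

    Rows violating the record invariants (``r`` outside [-1, 1], ``n`` < 3,
    unparseable numerics) are rejected with a logged reason and collected in
    ``RecordSet.rejected``; they are never silently dropped.

    Parameters
    ----------
    path
        CSV file with a header row naming at least ``r`` (other canonical
        columns optional).
    column_map
        Optional mapping ``{canonical_name: actual_header}`` adapting an
        externally deposited table to the canonical schema.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    if column_map:
        rename = {actual: canonical for canonical, actual in column_map.items()}
        frame = frame.rename(columns=rename)
    if "r" not in frame.columns:
        raise SchemaError(f"{path}: mandatory column 'r' missing")

    records: list[StatRecord] = []
    rejected: list[RejectedRow] = []
    seen_ids: set[str] = set()
    for row_index, raw in enumerate(frame.to_dict(orient="records")):
        try:
            rec = _parse_row(raw, row_index)
            if rec.record_id in seen_ids:
                raise ValueError(f"duplicate record_id {rec.record_id!r}")
        except ValueError as exc:
            logger.warning("%s: row %d rejected: %s", path, row_index, exc)
            rejected.append(RejectedRow(row_index, str(exc)))
            continue
        seen_ids.add(rec.record_id)
        records.append(rec)
    return RecordSet(records=records, provenance=str(path), rejected=rejected)


def write_records_csv(record_set: RecordSet, path: str | Path) -> None:
    """Write a :class:`RecordSet` in the canonical schema.

    Round-trips: ``read_records_csv(path)`` on the output reproduces the
    input field-by-field, preserving absent-vs-zero distinctions (absent
    fields become empty cells, never 0).
    """
    frame = record_set.to_frame()
    # pandas writes integer-valued floats as "230.0"; keep integer columns clean
    for col in ("n", "df", "year"):
        frame[col] = frame[col].map(lambda v: "" if pd.isna(v) else str(int(v)))
    frame.to_csv(path, index=False, na_rep="")


def merge_strata(
    record_set: RecordSet,
    mapping: Mapping[str, str],
    default: str | None = None,
) -> RecordSet:
    """Populate each record's ``subfield`` from its journal.

    Idempotent: applying the same mapping twice yields the same result.

    Raises
    ------
    KeyError
        If a journal is missing from ``mapping`` and no ``default`` is given.
    """
    merged = []
    for rec in record_set.records:
        journal = rec.journal
        if journal is None:
            subfield = default if default is not None else rec.subfield
        elif journal in mapping:
            subfield = mapping[journal]
        elif default is not None:
            subfield = default
        else:
            raise KeyError(f"journal {journal!r} not in subfield mapping and no default set")
        merged.append(replace(rec, subfield=subfield))
    return RecordSet(records=merged, provenance=record_set.provenance, rejected=record_set.rejected)
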