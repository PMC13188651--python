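"""Participant cohorts: domain records, CSV ingestion/writing, summary statistics.

A cohort holds one record per study participant: the procedure time in
decimal minutes (from tube insertion to confirmed selective lobar
ventilation), the self-reported prior-year endotracheal and double-lumen
intubation counts, and a completion flag.  All downstream inference runs
on the completed records' times; incomplete records are kept for audit
but excluded from every time analysis.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CSV_COLUMNS",
    "CohortError",
    "SchemaError",
    "ParseError",
    "ValidationError",
    "ParticipantRecord",
    "Cohort",
    "SummaryStats",
    "parse_time_minutes",
    "read_cohort",
    "write_cohort",
    "filter_by_experience",
    "summarize",
]

CSV_COLUMNS = (
    "participant_id",
    "time_minutes",
    "eti_prior_year",
    "dlt_prior_year",
    "completed",
)

_MSS_RE = re.compile(r"^\s*(\d+):([0-5]?\d(?:\.\d+)?)\s*$")
_TRUE = {"true", "t", "yes", "y", "1"}
_FALSE = {"false", "f", "no", "n", "0"}


class CohortError(ValueError):
    """Base class for cohort ingestion/validation failures."""


class SchemaError(CohortError):
    """The CSV header does not name a required column."""


class ParseError(CohortError):
    """A cell could not be parsed; the message names the row."""


class ValidationError(CohortError):
    """Record-level invariant violated (duplicate id, negative count, ...)."""


@dataclass(frozen=True)
class ParticipantRecord:
    """One participant's procedure time and prior-year experience counts."""

    participant_id: str
    time_minutes: float
    eti_prior_year: int
    dlt_prior_year: int
    completed: bool = True

    def __post_init__(self) -> None:
        if self.completed and not self.time_minutes > 0:
            raise ValidationError(
                f"record {self.participant_id!r}: completed record requires "
                f"time_minutes > 0, got {self.time_minutes}"
            )
        for name in ("eti_prior_year", "dlt_prior_year"):
            value = getattr(self, name)
            if not (isinstance(value, (int, np.integer)) and value >= 0):
                raise ValidationError(
                    f"record {self.participant_id!r}: {name} must be a "
                    f"non-negative integer, got {value!r}"
                )


@dataclass(frozen=True)
class Cohort:
    """Ordered, id-unique collection of participant records with provenance."""

    records: tuple[ParticipantRecord, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        ids = [r.participant_id for r in self.records]
        if len(set(ids)) != len(ids):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
            raise ValidationError(f"duplicate participant_id {dup!r}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ParticipantRecord]:
        return iter(self.records)

    @property
    def completed_records(self) -> tuple[ParticipantRecord, ...]:
        return tuple(r for r in self.records if r.completed)

    def times(self, completed_only: bool = True) -> np.ndarray:
        """Procedure times in minutes (by default, completers only)."""
        recs = self.completed_records if completed_only else self.records
        return np.array([r.time_minutes for r in recs], dtype=float)

    def eti_counts(self, completed_only: bool = True) -> np.ndarray:
        recs = self.completed_records if completed_only else self.records
        return np.array([r.eti_prior_year for r in recs], dtype=float)

    def dlt_counts(self, completed_only: bool = True) -> np.ndarray:
        recs = self.completed_records if completed_only else self.records
        return np.array([r.dlt_prior_year for r in recs], dtype=float)

    def with_provenance(self, provenance: str) -> "Cohort":
        return replace(self, provenance=provenance)


@dataclass(frozen=True)
class SummaryStats:
    """Moments and quartiles of a positive time sample.

    ``sd`` uses the n-1 denominator; quartiles use linear interpolation at
    plotting probability (k-1)/(n-1) ("type 7"), matching ``np.quantile``'s
    default.  ``cv`` is sd/mean (dimensionless).
    """

    n: int
    mean: float
    sd: float
    cv: float
    q25: float
    median: float
    q75: float
    min: float
    max: float


def parse_time_minutes(token: str | float | int) -> float:
    """Parse a time cell: decimal minutes or an ``m:ss`` string.

    ``"2:30"`` means 2 minutes 30 seconds -> 2.5.
    """
    if isinstance(token, (int, float, np.floating, np.integer)):
        return float(token)
    text = str(token).strip()
    m = _MSS_RE.match(text)
    if m:
        return float(m.group(1)) + float(m.group(2)) / 60.0
    try:
        return float(text)
    except ValueError as exc:
        raise ParseError(f"cannot parse time value {token!r}") from exc


def _parse_bool(token: str, row: int) -> bool:
    text = str(token).strip().lower()
    if text in _TRUE:
        return True
    if text in _FALSE:
        return False
    raise ParseError(f"row {row}: cannot parse completed flag {token!r}")


def _parse_count(token: str, row: int, column: str) -> int:
    text = str(token).strip()
    try:
        value = int(text)
    except ValueError as exc:
        raise ParseError(
            f"row {row}: non-integer {column} value {token!r}"
        ) from exc
    return value


def read_cohort(path) -> Cohort:
    """Read a cohort CSV (header: ``participant_id,time_minutes,eti_prior_year,dlt_prior_year,completed``).

    Rows are kept in file order.  Times may be decimal minutes or ``m:ss``
    strings; ``m:ss`` values are converted to decimal minutes on ingestion.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    if len(frame) == 0:
        raise CohortError(f"{path}: no data rows")
    records = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        raw_time = getattr(row, "time_minutes")
        try:
            time_minutes = parse_time_minutes(raw_time)
        except ParseError as exc:
            raise ParseError(f"row {i}: {exc}") from None
        records.append(
            ParticipantRecord(
                participant_id=str(getattr(row, "participant_id")).strip(),
                time_minutes=time_minutes,
                eti_prior_year=_parse_count(
                    getattr(row, "eti_prior_year"), i, "eti_prior_year"
                ),
                dlt_prior_year=_parse_count(
                    getattr(row, "dlt_prior_year"), i, "dlt_prior_year"
                ),
                completed=_parse_bool(getattr(row, "completed"), i),
            )
        )
    return Cohort(records=tuple(records), provenance=str(path))


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort CSV at full float precision (round-trip exact)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(CSV_COLUMNS) + "\n")
        for r in cohort.records:
            fh.write(
                f"{r.participant_id},{r.time_minutes!r},{r.eti_prior_year},"
                f"{r.dlt_prior_year},{str(r.completed).lower()}\n"
            )


def filter_by_experience(cohort: Cohort, min_eti: int) -> Cohort:
    """Retain records with ``eti_prior_year >= min_eti``, order preserved.

    An empty result is permitted and flagged in the provenance string.
    """
    if min_eti < 0:
        raise ValidationError(f"min_eti must be >= 0, got {min_eti}")
    kept = tuple(r for r in cohort.records if r.eti_prior_year >= min_eti)
    provenance = f"{cohort.provenance} | filter eti>={min_eti}"
    if not kept:
        provenance += " (empty result)"
    return Cohort(records=kept, provenance=provenance)


def summarize(times: Sequence[float] | np.ndarray) -> SummaryStats:
    """Summary statistics of a positive time sample (minutes)."""
    x = np.asarray(times, dtype=float)
    if x.size == 0:
        raise CohortError("cannot summarize an empty sample")
    if np.any(x <= 0):
        raise ValidationError("times must be positive for CV to be meaningful")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    q25, median, q75 = (float(q) for q in np.quantile(x, [0.25, 0.5, 0.75]))
    return SummaryStats(
        n=int(x.size),
        mean=mean,
        sd=sd,
        cv=sd / mean,
        q25=q25,
        median=median,
        q75=q75,
        min=float(np.min(x)),
        max=float(np.max(x)),
    )
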