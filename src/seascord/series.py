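"""Monthly count tables and persons-per-thousand proportion series.

The study pipeline starts from long-format tables of monthly event counts:
for each series (a condition concept in the observational-health setting),
each calendar month carries the number of distinct persons with the event
and the number of persons under observation that month.  These are turned
into monthly proportion series (persons per 1,000 persons observed),
trimmed to complete calendar years, with a four-complete-year eligibility
floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MonthlyCountRecord",
    "MonthlyCountSeries",
    "ProportionSeries",
    "SeriesError",
    "IneligibleSeriesError",
    "read_counts",
    "read_proportions",
    "trim_to_complete_years",
    "to_proportion_series",
    "write_proportions",
    "write_counts",
]

COUNT_COLUMNS = ["series_id", "year", "month", "event_persons", "denominator_persons"]
PROPORTION_COLUMNS = ["series_id", "year", "month", "value"]


class SeriesError(ValueError):
    """Invalid or inconsistent monthly count input."""


class IneligibleSeriesError(SeriesError):
    """Series does not meet the four-complete-year eligibility floor."""

    def __init__(self, series_id, complete_years: int):
        self.series_id = series_id
        self.complete_years = complete_years
        super().__init__(
            f"series {series_id!r}: only {complete_years} complete calendar "
            f"year(s); at least 4 are required"
        )


@dataclass(frozen=True)
class MonthlyCountRecord:
    """One month of one series: distinct persons with the event and persons observed."""

    series_id: str
    year: int
    month: int
    event_persons: int
    denominator_persons: int

    def __post_init__(self):
        if not 1 <= self.month <= 12:
            raise SeriesError(
                f"series {self.series_id!r} {self.year}-{self.month:02d}: "
                f"month must be in 1..12"
            )
        if self.event_persons < 0:
            raise SeriesError(
                f"series {self.series_id!r} {self.year}-{self.month:02d}: "
                f"negative event_persons"
            )
        if self.denominator_persons < 0:
            raise SeriesError(
                f"series {self.series_id!r} {self.year}-{self.month:02d}: "
                f"negative denominator_persons"
            )
        if self.event_persons > self.denominator_persons:
            raise SeriesError(
                f"series {self.series_id!r} {self.year}-{self.month:02d}: "
                f"event_persons ({self.event_persons}) exceeds "
                f"denominator_persons ({self.denominator_persons})"
            )


@dataclass
class MonthlyCountSeries:
    """Calendar-ordered monthly count records for a single series."""

    series_id: str
    records: list[MonthlyCountRecord]

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (r.series_id, r.year, r.month, r.event_persons, r.denominator_persons)
                for r in self.records
            ],
            columns=COUNT_COLUMNS,
        )


@dataclass
class ProportionSeries:
    """Complete monthly series of persons-per-thousand values.

    Anchored at (start_year, start_month); values run in calendar order with
    seasonal period 12.  Eligible series span whole calendar years (length a
    multiple of 12, at least 48).
    """

    series_id: str
    start_year: int
    start_month: int
    values: np.ndarray
    period: int = 12

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise SeriesError("values must be one-dimensional")
        if np.any(self.values < 0):
            raise SeriesError(f"series {self.series_id!r}: negative proportion values")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def n_years(self) -> int:
        return self.n // 12

    def month_of(self, t: int) -> int:
        """Calendar month (1-12) of the 0-based position ``t``."""
        return (self.start_month - 1 + t) % 12 + 1

    def calendar_index(self) -> list[tuple[int, int]]:
        """(year, month) pairs for every position."""
        out = []
        y, m = self.start_year, self.start_month
        for _ in range(self.n):
            out.append((y, m))
            m += 1
            if m == 13:
                m, y = 1, y + 1
        return out

    def validate_eligible(self) -> None:
        if self.n % 12 != 0 or self.n < 48 or self.start_month != 1:
            raise IneligibleSeriesError(self.series_id, self.n // 12)

    def to_frame(self) -> pd.DataFrame:
        idx = self.calendar_index()
        return pd.DataFrame(
            {
                "series_id": self.series_id,
                "year": [y for y, _ in idx],
                "month": [m for _, m in idx],
                "value": self.values,
            }
        )


def _month_key(year: int, month: int) -> int:
    return year * 12 + (month - 1)


def _read_delimited(source, required: Sequence[str]) -> pd.DataFrame:
    """Read a comma- or tab-delimited table with a header row."""
    df = pd.read_csv(source, sep=None, engine="python")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SeriesError(f"input table is missing column(s): {', '.join(missing)}")
    return df


def read_counts(source) -> dict[str, MonthlyCountSeries]:
    """Load a long-format monthly count table into per-series objects.

    ``source`` is a path or file handle of delimited text (comma default,
    tab accepted) with header columns ``series_id, year, month,
    event_persons, denominator_persons``.  Records are sorted by (year,
    month) within each series.  Duplicate (series_id, year, month) keys,
    months outside 1-12 and event counts exceeding denominators are
    rejected.
    """
    df = _read_delimited(source, COUNT_COLUMNS)
    dup = df.duplicated(subset=["series_id", "year", "month"], keep=False)
    if dup.any():
        row = df.loc[dup].iloc[0]
        raise SeriesError(
            f"duplicate key (series_id={row['series_id']!r}, "
            f"year={int(row['year'])}, month={int(row['month'])}) in input table"
        )
    out: dict[str, MonthlyCountSeries] = {}
    for sid, grp in df.groupby("series_id", sort=True):
        grp = grp.sort_values(["year", "month"])
        records = [
            MonthlyCountRecord(
                series_id=str(sid),
                year=int(r.year),
                month=int(r.month),
                event_persons=int(r.event_persons),
                denominator_persons=int(r.denominator_persons),
            )
            for r in grp.itertuples()
        ]
        out[str(sid)] = MonthlyCountSeries(series_id=str(sid), records=records)
    return out


def read_proportions(source) -> dict[str, ProportionSeries]:
    """Load pre-built proportion series from delimited text.

    Columns: ``series_id, year, month, value``.  Each series must be
    calendar-contiguous.
    """
    df = _read_delimited(source, PROPORTION_COLUMNS)
    out: dict[str, ProportionSeries] = {}
    for sid, grp in df.groupby("series_id", sort=True):
        grp = grp.sort_values(["year", "month"])
        keys = [_month_key(int(y), int(m)) for y, m in zip(grp["year"], grp["month"])]
        if any(b - a != 1 for a, b in zip(keys, keys[1:])):
            raise SeriesError(f"series {sid!r}: calendar gap in proportion table")
        out[str(sid)] = ProportionSeries(
            series_id=str(sid),
            start_year=int(grp["year"].iloc[0]),
            start_month=int(grp["month"].iloc[0]),
            values=grp["value"].to_numpy(dtype=float),
        )
    return out


def trim_to_complete_years(series: MonthlyCountSeries) -> MonthlyCountSeries:
    """Drop leading/trailing partial calendar years; enforce eligibility.

    Every retained year must have exactly 12 monthly records and the months
    must be contiguous (an interior gap makes the series ineligible: a
    missing month is missing data, not a zero).  Fewer than four surviving
    complete years raises :class:`IneligibleSeriesError` carrying the count
    found.  Idempotent.
    """
    by_year: dict[int, list[MonthlyCountRecord]] = {}
    for rec in series.records:
        by_year.setdefault(rec.year, []).append(rec)

    complete: list[int] = []
    for year in sorted(by_year):
        months = sorted(r.month for r in by_year[year])
        if months == list(range(1, 13)):
            complete.append(year)

    # keep the longest run of consecutive complete years containing no gaps
    runs: list[list[int]] = []
    for y in complete:
        if runs and y == runs[-1][-1] + 1:
            runs[-1].append(y)
        else:
            runs.append([y])
    best = max(runs, key=len, default=[])
    if len(best) < 4:
        raise IneligibleSeriesError(series.series_id, len(best))

    records = [
        rec
        for year in best
        for rec in sorted(by_year[year], key=lambda r: r.month)
    ]
    return MonthlyCountSeries(series_id=series.series_id, records=records)


def to_proportion_series(series: MonthlyCountSeries) -> ProportionSeries:
    """Persons-per-thousand proportions: 1000 * event / denominator per month.

    The input must already be trimmed to complete years (see
    :func:`trim_to_complete_years`).  A zero denominator in any retained
    month is an error naming that month.
    """
    if not series.records:
        raise SeriesError(f"series {series.series_id!r}: empty series")
    values = np.empty(len(series.records))
    for i, rec in enumerate(series.records):
        if rec.denominator_persons == 0:
            raise SeriesError(
                f"series {series.series_id!r} {rec.year}-{rec.month:02d}: "
                f"zero denominator_persons"
            )
        values[i] = 1000.0 * rec.event_persons / rec.denominator_persons
    first = series.records[0]
    return ProportionSeries(
        series_id=series.series_id,
        start_year=first.year,
        start_month=first.month,
        values=values,
    )


def build_proportion_series(
    counts: Mapping[str, MonthlyCountSeries],
) -> tuple[dict[str, ProportionSeries], dict[str, IneligibleSeriesError]]:
    """Trim and convert a collection of count series; partition by eligibility."""
    eligible: dict[str, ProportionSeries] = {}
    rejected: dict[str, IneligibleSeriesError] = {}
    for sid, cs in counts.items():
        try:
            eligible[sid] = to_proportion_series(trim_to_complete_years(cs))
        except IneligibleSeriesError as err:
            rejected[sid] = err
    return eligible, rejected


def write_proportions(series: Iterable[ProportionSeries], path, float_format="%.10g") -> None:
    """Write proportion series as delimited text (round-trips through read)."""
    frames = [s.to_frame() for s in series]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format=float_format)


def write_counts(series: Iterable[MonthlyCountSeries], path) -> None:
    frames = [s.to_frame() for s in series]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
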