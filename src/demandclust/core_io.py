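"""Core domain types and CSV input/output for daily intermittent demand data.

The package works on three containers:

* :class:`EventLog` — individual demand arrivals with minute-resolution
  timestamps, the raw form in which teleconsultation-style requests are
  recorded and the form needed for waiting-time analysis.
* :class:`DemandSeries` — one non-negative integer count per calendar day,
  the form consumed by feature construction, clustering and forecasting.
* :class:`Calendar` — the observation window plus holiday intervals, which
  carries the week bookkeeping used by the service-analysis module.

Two plain-text exchange formats are supported, both via pandas: a long event
log CSV (``series_id,timestamp`` with ISO-8601 timestamps) and a wide daily
matrix CSV (first column ``date``, one column of counts per series).
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Calendar",
    "DemandSeries",
    "EventLog",
    "aggregate_daily",
    "filter_by_total_demand",
    "read_daily_matrix",
    "read_event_log",
    "study_calendar",
    "write_daily_matrix",
    "write_event_log",
]


class EventLogParseError(ValueError):
    """Raised when an event-log CSV has a malformed row."""


@dataclass(frozen=True)
class Calendar:
    """Observation window (inclusive dates) with holiday intervals.

    Weeks are 7-day blocks counted from the window start; the number of
    calendar weeks is ``ceil(n_days / 7)``.  A week is a *holiday week* if it
    intersects any holiday interval.  Holiday intervals are closed date
    ranges and must lie inside the window.
    """

    start: dt.date
    end: dt.date
    holidays: tuple[tuple[dt.date, dt.date], ...] = ()

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("calendar end precedes start")
        for h0, h1 in self.holidays:
            if h1 < h0:
                raise ValueError(f"holiday interval {h0}..{h1} reversed")
            if h0 < self.start or h1 > self.end:
                raise ValueError(f"holiday interval {h0}..{h1} outside window")

    @property
    def n_days(self) -> int:
        return (self.end - self.start).days + 1

    @property
    def n_weeks(self) -> int:
        return math.ceil(self.n_days / 7)

    @property
    def n_holiday_weeks(self) -> int:
        """Number of week blocks intersecting at least one holiday interval."""
        weeks: set[int] = set()
        for h0, h1 in self.holidays:
            weeks.update(range(self.day_index(h0) // 7, self.day_index(h1) // 7 + 1))
        return len(weeks)

    def day_index(self, d: dt.date) -> int:
        """0-based offset of a date from the window start."""
        i = (d - self.start).days
        if i < 0 or i >= self.n_days:
            raise ValueError(f"date {d} outside calendar window")
        return i

    def date_of(self, index: int) -> dt.date:
        if index < 0 or index >= self.n_days:
            raise ValueError(f"day index {index} outside calendar window")
        return self.start + dt.timedelta(days=index)

    def is_holiday(self, d: dt.date) -> bool:
        return any(h0 <= d <= h1 for h0, h1 in self.holidays)

    def holiday_mask(self) -> np.ndarray:
        """Boolean mask over day indices, True on holiday days."""
        mask = np.zeros(self.n_days, dtype=bool)
        for h0, h1 in self.holidays:
            mask[self.day_index(h0) : self.day_index(h1) + 1] = True
        return mask

    def weekdays(self) -> np.ndarray:
        """Weekday (Mon=0..Sun=6) of every day in the window."""
        first = self.start.weekday()
        return (first + np.arange(self.n_days)) % 7


def study_calendar() -> Calendar:
    """The default 99-week observation window used throughout the package.

    693 days starting Monday 2018-01-01 (exactly 99 weeks), with four
    week-aligned 7-day holidays (two winter festivals, two national-day
    weeks), leaving 95 service weeks.
    """
    return Calendar(
        start=dt.date(2018, 1, 1),
        end=dt.date(2019, 11, 24),
        holidays=(
            (dt.date(2018, 2, 12), dt.date(2018, 2, 18)),
            (dt.date(2018, 10, 1), dt.date(2018, 10, 7)),
            (dt.date(2019, 2, 4), dt.date(2019, 2, 10)),
            (dt.date(2019, 9, 30), dt.date(2019, 10, 6)),
        ),
    )


@dataclass(frozen=True)
class DemandSeries:
    """Daily demand counts for one department, dated from ``start_date``."""

    series_id: str
    start_date: dt.date
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 1 or counts.size < 1:
            raise ValueError("counts must be a non-empty 1-D sequence")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    def __len__(self) -> int:
        return int(self.counts.size)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def dates(self) -> list[dt.date]:
        return [self.start_date + dt.timedelta(days=i) for i in range(len(self))]

    def nonzero_days(self) -> np.ndarray:
        """0-based day indices with at least one demand."""
        return np.flatnonzero(self.counts)

    def nonzero_sizes(self) -> np.ndarray:
        return self.counts[self.counts > 0]


@dataclass(frozen=True)
class EventLog:
    """Timestamped demand arrivals (minute resolution) for one department."""

    series_id: str
    arrivals: tuple[dt.datetime, ...]

    def __post_init__(self) -> None:
        arr = tuple(self.arrivals)
        if any(b < a for a, b in zip(arr, arr[1:])):
            raise ValueError("arrivals must be non-decreasing")
        object.__setattr__(self, "arrivals", arr)

    def __len__(self) -> int:
        return len(self.arrivals)


def read_event_log(path) -> list[EventLog]:
    """Read an event-log CSV (columns ``series_id,timestamp``) into EventLogs.

    Returns one :class:`EventLog` per distinct series id (sorted by id),
    arrivals sorted within each log.  A malformed timestamp raises
    :class:`EventLogParseError` naming the offending row.
    """
    try:
        df = pd.read_csv(path, dtype={"series_id": str})
    except pd.errors.EmptyDataError:
        return []
    if df.empty:
        return []
    if not {"series_id", "timestamp"} <= set(df.columns):
        raise EventLogParseError("event log needs columns series_id,timestamp")
    ts = pd.to_datetime(df["timestamp"], errors="coerce")
    if ts.isna().any():
        row = int(np.flatnonzero(ts.isna().to_numpy())[0])
        raise EventLogParseError(
            f"malformed timestamp {df['timestamp'].iloc[row]!r} at data row {row}"
        )
    df = df.assign(timestamp=ts)
    logs = []
    for sid, grp in df.groupby("series_id", sort=True):
        arrivals = tuple(t.to_pydatetime() for t in grp["timestamp"].sort_values())
        logs.append(EventLog(series_id=str(sid), arrivals=arrivals))
    return logs


def write_event_log(logs: Iterable[EventLog], path) -> None:
    rows = [
        {"series_id": log.series_id, "timestamp": t.isoformat(timespec="minutes")}
        for log in logs
        for t in log.arrivals
    ]
    pd.DataFrame(rows, columns=["series_id", "timestamp"]).to_csv(path, index=False)


def aggregate_daily(log: EventLog, cal: Calendar) -> DemandSeries:
    """Collapse an event log to daily counts over the calendar window.

    Days with no arrival get a zero count; an arrival outside the window is a
    range error.  Summing the result recovers the number of arrivals.
    """
    counts = np.zeros(cal.n_days, dtype=np.int64)
    for t in log.arrivals:
        counts[cal.day_index(t.date())] += 1
    return DemandSeries(series_id=log.series_id, start_date=cal.start, counts=counts)


def filter_by_total_demand(
    series_set: Sequence[DemandSeries], min_total: int = 51
) -> tuple[list[DemandSeries], list[DemandSeries]]:
    """Partition series into (kept, removed) by total demand over the window.

    Series with very small totals are too sporadic to classify meaningfully;
    the default keeps series with more than 50 demands.
    """
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    kept = [s for s in series_set if s.total >= min_total]
    removed = [s for s in series_set if s.total < min_total]
    return kept, removed


def write_daily_matrix(series_set: Sequence[DemandSeries], path) -> None:
    """Write a wide daily-count CSV: first column date, one column per series."""
    if not series_set:
        pd.DataFrame(columns=["date"]).to_csv(path, index=False)
        return
    starts = {s.start_date for s in series_set}
    lengths = {len(s) for s in series_set}
    if len(starts) > 1 or len(lengths) > 1:
        raise ValueError("all series must share start date and length")
    df = pd.DataFrame({s.series_id: s.counts for s in series_set})
    df.insert(0, "date", [d.isoformat() for d in series_set[0].dates()])
    df.to_csv(path, index=False)


def read_daily_matrix(path) -> list[DemandSeries]:
    df = pd.read_csv(path)
    if df.empty or df.shape[1] < 2:
        return []
    dates = pd.to_datetime(df.iloc[:, 0]).dt.date
    start = dates.iloc[0]
    return [
        DemandSeries(series_id=str(col), start_date=start, counts=df[col].to_numpy())
        for col in df.columns[1:]
    ]
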