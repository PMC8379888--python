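"""Service efficiency and quality analysis for intermittent demand.

Efficiency is measured by the ratio of demand days to service days (a
department with demand on few days should not be staffed every day), and
quality by the mean patient waiting time from each arrival to the first
service occasion at or after it.  Fixed weekly strategies — a constant
number of service occasions per week on fixed weekdays at a fixed time of
day (17:00 by default, noon on Saturdays) — provide the ideal benchmark
against which actual service is compared.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core_io import Calendar, EventLog

__all__ = [
    "FixedStrategy",
    "GapReport",
    "ServiceLog",
    "ServiceReport",
    "actual_metrics",
    "ideal_service_times",
    "schedule_services",
    "strategy_gap",
    "waiting_time_gap",
]

WEEKDAY_NAMES = ("monday", "tuesday", "wednesday", "thursday", "friday", "saturday", "sunday")


@dataclass(frozen=True)
class ServiceLog:
    """Timestamps at which service was provided for one department."""

    series_id: str
    times: tuple[dt.datetime, ...]

    def __post_init__(self) -> None:
        t = tuple(self.times)
        if any(b < a for a, b in zip(t, t[1:])):
            raise ValueError("service times must be non-decreasing")
        object.__setattr__(self, "times", t)


@dataclass(frozen=True)
class FixedStrategy:
    """A fixed weekly service schedule.

    Either ``services_per_week`` with matching ``service_days`` (weekday
    numbers, Mon=0), or ``next_day=True`` meaning service on the day after
    each demand day.  Service occurs at ``service_time`` (Saturdays at
    ``saturday_time``).
    """

    services_per_week: int = 0
    service_days: tuple[int, ...] = ()
    service_time: dt.time = dt.time(17, 0)
    saturday_time: dt.time = dt.time(12, 0)
    next_day: bool = False

    def __post_init__(self) -> None:
        if self.next_day:
            return
        if self.services_per_week < 0:
            raise ValueError("services_per_week must be >= 0")
        if len(set(self.service_days)) != len(self.service_days):
            raise ValueError("duplicate service days")
        if any(d < 0 or d > 6 for d in self.service_days):
            raise ValueError("service days must be weekday numbers 0..6")
        if len(self.service_days) != self.services_per_week:
            raise ValueError("|service_days| must equal services_per_week")


@dataclass(frozen=True)
class ServiceReport:
    """Efficiency/quality metrics of a (demand, service) pair of logs."""

    demand_days: float
    service_days: float
    ratio: float
    mean_wait_h: float
    intervals_per_week: float
    mean_interval_len_d: float
    n_unserved: int = 0
    ideal_service_times: int | None = None


def _holiday_weeks(cal: Calendar) -> set[int]:
    weeks: set[int] = set()
    for h0, h1 in cal.holidays:
        weeks.update(range(cal.day_index(h0) // 7, cal.day_index(h1) // 7 + 1))
    return weeks


def ideal_service_times(strategy: FixedStrategy, cal: Calendar) -> int:
    """Ideal number of service occasions: services/week × non-holiday weeks."""
    if strategy.next_day:
        raise ValueError("ideal service times undefined for next-day strategies")
    return strategy.services_per_week * (cal.n_weeks - cal.n_holiday_weeks)


def _service_datetime(date: dt.date, strategy: FixedStrategy) -> dt.datetime:
    t = strategy.saturday_time if date.weekday() == 5 else strategy.service_time
    return dt.datetime.combine(date, t)


def schedule_services(
    strategy: FixedStrategy,
    cal: Calendar,
    demand_log: EventLog | None = None,
    series_id: str = "strategy",
) -> ServiceLog:
    """Materialise a fixed strategy into a service log over the calendar.

    Weekly mode: one occasion per listed weekday in every non-holiday week
    (holiday days themselves are also skipped).  Next-day mode: one occasion
    on the day after each demand day of ``demand_log``.
    """
    if strategy.next_day:
        if demand_log is None:
            raise ValueError("next-day strategy needs a demand EventLog")
        demand_dates = sorted({t.date() for t in demand_log.arrivals})
        times = []
        for d in demand_dates:
            nxt = d + dt.timedelta(days=1)
            if nxt > cal.end:
                continue
            times.append(_service_datetime(nxt, strategy))
        return ServiceLog(series_id=series_id, times=tuple(sorted(times)))

    hweeks = _holiday_weeks(cal)
    times = []
    for i in range(cal.n_days):
        if i // 7 in hweeks:
            continue
        date = cal.date_of(i)
        if cal.is_holiday(date):
            continue
        if date.weekday() in strategy.service_days:
            times.append(_service_datetime(date, strategy))
    return ServiceLog(series_id=series_id, times=tuple(sorted(times)))


def actual_metrics(log: EventLog, svc: ServiceLog, cal: Calendar) -> ServiceReport:
    """Efficiency/quality metrics for one demand log against one service log.

    * demand_days / service_days: number of distinct days with >= 1 arrival
      / occasion, and their ratio (error if no service day).
    * mean_wait_h: mean hours from each arrival to the first service at or
      after it; arrivals with no later service are flagged, warned about and
      excluded.
    * intervals: maximal runs of zero-demand days strictly between demand
      days; reported per calendar week and as a mean run length.
    """
    for t in log.arrivals:
        cal.day_index(t.date())
    for t in svc.times:
        cal.day_index(t.date())

    demand_days = len({t.date() for t in log.arrivals})
    service_days = len({t.date() for t in svc.times})
    if service_days == 0:
        raise ValueError("no service days: ratio undefined")
    ratio = demand_days / service_days

    svc_times = np.array(sorted(svc.times), dtype="datetime64[m]")
    arr_times = np.array(list(log.arrivals), dtype="datetime64[m]")
    if arr_times.size:
        idx = np.searchsorted(svc_times, arr_times, side="left")
        served = idx < svc_times.size
        n_unserved = int((~served).sum())
        if n_unserved:
            warnings.warn(
                f"{n_unserved} arrival(s) in {log.series_id!r} have no later "
                "service occasion; excluded from mean wait"
            )
        if served.any():
            waits = (svc_times[idx[served]] - arr_times[served]).astype(
                "timedelta64[m]"
            ).astype(float) / 60.0
            mean_wait = float(waits.mean())
        else:
            mean_wait = float("nan")
    else:
        n_unserved = 0
        mean_wait = float("nan")

    ddays = np.unique([cal.day_index(t.date()) for t in log.arrivals])
    gaps = np.diff(ddays)
    runs = gaps[gaps > 1] - 1
    n_runs = int(runs.size)
    return ServiceReport(
        demand_days=float(demand_days),
        service_days=float(service_days),
        ratio=float(ratio),
        mean_wait_h=mean_wait,
        intervals_per_week=n_runs / cal.n_weeks,
        mean_interval_len_d=float(runs.mean()) if n_runs else 0.0,
        n_unserved=n_unserved,
    )


@dataclass(frozen=True)
class GapReport:
    """Actual-vs-strategy comparison for one demand log."""

    strategy_report: ServiceReport = field(repr=False)
    wait_gap_h: float
    service_days_gap: float


def waiting_time_gap(actual: ServiceReport, under_strategy: ServiceReport) -> float:
    """Hours by which actual mean waiting time exceeds the strategy's."""
    return actual.mean_wait_h - under_strategy.mean_wait_h


def strategy_gap(
    log: EventLog,
    strategy: FixedStrategy,
    cal: Calendar,
    actual: ServiceReport,
) -> GapReport:
    """Evaluate a fixed strategy on a demand log and compare with actual service.

    Reports the waiting-time gap (actual mean wait − mean wait under the
    scheduled strategy) and the service-day gap (actual service days − ideal
    service times; for next-day strategies, minus the scheduled occasions).
    """
    svc = schedule_services(strategy, cal, demand_log=log)
    under = actual_metrics(log, svc, cal)
    if strategy.next_day:
        ideal = len({t.date() for t in svc.times})
    else:
        ideal = ideal_service_times(strategy, cal)
    under = ServiceReport(
        demand_days=under.demand_days,
        service_days=under.service_days,
        ratio=under.ratio,
        mean_wait_h=under.mean_wait_h,
        intervals_per_week=under.intervals_per_week,
        mean_interval_len_d=under.mean_interval_len_d,
        n_unserved=under.n_unserved,
        ideal_service_times=int(ideal),
    )
    return GapReport(
        strategy_report=under,
        wait_gap_h=waiting_time_gap(actual, under),
        service_days_gap=actual.service_days - ideal,
    )
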