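import datetime as dt

import numpy as np
import pytest

from demandclust import (
    Calendar,
    EventLog,
    FixedStrategy,
    ServiceLog,
    ServiceReport,
    actual_metrics,
    ideal_service_times,
    schedule_services,
    strategy_gap,
    study_calendar,
    waiting_time_gap,
)


def weekly(*days):
    return FixedStrategy(services_per_week=len(days), service_days=tuple(days))


class TestIdealServiceTimes:
    def test_study_calendar_arithmetic(self):
        cal = study_calendar()
        # 99 calendar weeks minus 4 holiday weeks = 95 service weeks
        assert cal.n_weeks - cal.n_holiday_weeks == 95
        assert ideal_service_times(weekly(0, 1, 2, 3, 5), cal) == 475
        assert ideal_service_times(weekly(2, 4), cal) == 190
        assert ideal_service_times(FixedStrategy(), cal) == 0

    def test_linear_in_services_per_week(self):
        cal = study_calendar()
        base = ideal_service_times(weekly(0), cal)
        for k, days in [(2, (0, 2)), (3, (0, 2, 4)), (4, (0, 1, 2, 3))]:
            assert ideal_service_times(weekly(*days), cal) == k * base

    def test_next_day_has_no_ideal_count(self):
        with pytest.raises(ValueError):
            ideal_service_times(FixedStrategy(next_day=True), study_calendar())


class TestScheduleServices:
    def test_two_per_week_wed_fri(self, week_cal):
        svc = schedule_services(weekly(2, 4), week_cal)
        assert [t.isoformat() for t in svc.times] == [
            "2022-01-05T17:00:00",
            "2022-01-07T17:00:00",
        ]

    def test_holiday_week_has_no_service(self):
        cal = Calendar(
            start=dt.date(2022, 1, 3),
            end=dt.date(2022, 1, 16),
            holidays=((dt.date(2022, 1, 3), dt.date(2022, 1, 9)),),
        )
        svc = schedule_services(weekly(2, 4), cal)
        assert all(t.date() >= dt.date(2022, 1, 10) for t in svc.times)
        assert len(svc.times) == 2

    def test_saturday_service_is_at_noon(self, week_cal):
        svc = schedule_services(weekly(0, 1, 2, 3, 5), week_cal)
        by_dow = {t.weekday(): t for t in svc.times}
        assert by_dow[5].time() == dt.time(12, 0)
        assert by_dow[0].time() == dt.time(17, 0)

    def test_next_day_mode(self, week_cal):
        log = EventLog("a", (dt.datetime(2022, 1, 3, 9), dt.datetime(2022, 1, 5, 15)))
        svc = schedule_services(FixedStrategy(next_day=True), week_cal, demand_log=log)
        assert [t.date().isoformat() for t in svc.times] == ["2022-01-04", "2022-01-06"]

    def test_next_day_without_log_rejected(self, week_cal):
        with pytest.raises(ValueError):
            schedule_services(FixedStrategy(next_day=True), week_cal)

    def test_mismatched_day_count_rejected(self):
        with pytest.raises(ValueError):
            FixedStrategy(services_per_week=2, service_days=(0,))


class TestActualMetrics:
    def test_same_day_wait_is_eight_hours(self, week_cal):
        log = EventLog("a", (dt.datetime(2022, 1, 3, 9),))
        svc = ServiceLog("a", (dt.datetime(2022, 1, 3, 17),))
        rep = actual_metrics(log, svc, week_cal)
        assert rep.mean_wait_h == pytest.approx(8.0)
        assert rep.demand_days == 1 and rep.service_days == 1 and rep.ratio == 1.0

    def test_zero_run_between_demand_days(self, week_cal):
        # demand on days 0,1,5,6 -> one zero run (days 2-4) of length 3
        arrivals = tuple(
            dt.datetime(2022, 1, 3 + d, 10) for d in (0, 1, 5, 6)
        )
        svc = ServiceLog("a", (dt.datetime(2022, 1, 9, 17),))
        rep = actual_metrics(EventLog("a", arrivals), svc, week_cal)
        assert rep.intervals_per_week == pytest.approx(1.0)
        assert rep.mean_interval_len_d == pytest.approx(3.0)

    def test_no_service_days_is_an_error(self, week_cal):
        log = EventLog("a", (dt.datetime(2022, 1, 3, 9),))
        with pytest.raises(ValueError, match="ratio"):
            actual_metrics(log, ServiceLog("a", ()), week_cal)

    def test_unserved_arrival_flagged_and_excluded(self, week_cal):
        log = EventLog(
            "a", (dt.datetime(2022, 1, 3, 9), dt.datetime(2022, 1, 8, 9))
        )
        svc = ServiceLog("a", (dt.datetime(2022, 1, 3, 17),))
        with pytest.warns(UserWarning, match="no later service"):
            rep = actual_metrics(log, svc, week_cal)
        assert rep.n_unserved == 1
        assert rep.mean_wait_h == pytest.approx(8.0)

    def test_denser_schedule_never_increases_mean_wait(self):
        cal = study_calendar()
        rng = np.random.default_rng(4)
        days = np.sort(rng.choice(600, size=40, replace=False))
        arrivals = tuple(
            dt.datetime.combine(cal.date_of(int(d)), dt.time(9, 0)) for d in days
        )
        log = EventLog("a", arrivals)
        sparse = schedule_services(weekly(2), cal)
        dense = schedule_services(weekly(2, 4), cal)  # superset of service days
        w_sparse = actual_metrics(log, sparse, cal).mean_wait_h
        w_dense = actual_metrics(log, dense, cal).mean_wait_h
        assert w_dense <= w_sparse

    def test_agrees_with_brute_force_oracle(self, week_cal):
        rng = np.random.default_rng(5)
        for _ in range(60):
            n = int(rng.integers(1, 15))
            arr = sorted(
                dt.datetime(2022, 1, 3 + int(d), int(h), int(m))
                for d, h, m in zip(
                    rng.integers(0, 7, n), rng.integers(0, 24, n), rng.integers(0, 60, n)
                )
            )
            m = int(rng.integers(1, 6))
            svc = sorted(
                dt.datetime(2022, 1, 3 + int(d), int(h))
                for d, h in zip(rng.integers(0, 7, m), rng.integers(0, 24, m))
            )
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rep = actual_metrics(
                    EventLog("a", tuple(arr)), ServiceLog("a", tuple(svc)), week_cal
                )
            waits = []
            for a in arr:
                later = [t for t in svc if t >= a]
                if later:
                    waits.append((min(later) - a).total_seconds() / 3600)
            if waits:
                assert rep.mean_wait_h == pytest.approx(np.mean(waits))
            assert rep.n_unserved == len(arr) - len(waits)
            assert rep.demand_days == len({a.date() for a in arr})
            assert rep.service_days == len({t.date() for t in svc})


class TestStrategyGap:
    def _report(self, wait):
        return ServiceReport(
            demand_days=1, service_days=1, ratio=1.0, mean_wait_h=wait,
            intervals_per_week=0.0, mean_interval_len_d=0.0,
        )

    def test_gap_is_difference_of_mean_waits(self):
        assert waiting_time_gap(self._report(30.86), self._report(9.15)) == pytest.approx(21.71)

    def test_identical_service_gives_zero_gap(self):
        cal = study_calendar()
        rng = np.random.default_rng(6)
        days = np.sort(rng.choice(600, size=30, replace=False))
        log = EventLog(
            "a",
            tuple(dt.datetime.combine(cal.date_of(int(d)), dt.time(9, 0)) for d in days),
        )
        strat = weekly(2, 4)
        svc = schedule_services(strat, cal)
        actual = actual_metrics(log, svc, cal)
        gap = strategy_gap(log, strat, cal, actual)
        assert gap.wait_gap_h == pytest.approx(0.0)
        assert gap.strategy_report.ideal_service_times == ideal_service_times(strat, cal)
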