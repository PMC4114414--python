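"""Daily summaries and the four per-participant Lifespace metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lifespace.metrics import (
    daily_summaries,
    max_distance,
    mean_daily_distance,
    pct_time_at_home,
    trips_per_week,
)
from lifespace.traces import Trace

from conftest import T0, trace_from_distances


class TestMaxDistance:
    def test_all_at_home(self, home, make_trace):
        assert max_distance(make_trace([0.0] * 10), home) == pytest.approx(0.0, abs=1e-9)

    def test_single_far_fix_sets_maximum(self, home, make_trace):
        d = max_distance(make_trace([0.0] * 20 + [67.0] + [0.0] * 20), home)
        assert d == pytest.approx(67.0, rel=1e-4)

    def test_empty_is_undefined_not_zero(self, home, make_trace):
        assert max_distance(make_trace([]), home) is None

    def test_monotone_under_added_fix(self, home, make_trace):
        base = [0.0, 1.0, 3.0]
        d1 = max_distance(make_trace(base), home)
        d2 = max_distance(make_trace(base + [0.2]), home)
        assert d2 >= d1


class TestDailySummaries:
    def test_stationary_hour_at_home(self, home, make_trace):
        trace = make_trace([0.0] * 361, step=pd.Timedelta(seconds=10))
        (day,) = daily_summaries(trace, home)
        assert day.recorded_seconds == pytest.approx(3600)
        assert day.seconds_at_home == pytest.approx(3600)
        assert day.path_length_km == pytest.approx(0.0, abs=1e-9)

    def test_out_and_back_path_and_max(self, home):
        # straight line out 5 km and back, 0.5 km per minute-fix
        out = list(np.arange(0, 5.5, 0.5))
        trace = trace_from_distances(out + out[-2::-1])
        (day,) = daily_summaries(trace, home)
        assert day.path_length_km == pytest.approx(10.0, rel=1e-6)
        assert day.max_home_distance_km == pytest.approx(5.0, rel=1e-6)

    def test_two_days_two_summaries(self, home):
        a = trace_from_distances([0.0] * 10)
        b = trace_from_distances([0.0] * 10, start=T0 + pd.Timedelta(days=2))
        trace = Trace.from_records(
            "t",
            list(a.points["timestamp"]) + list(b.points["timestamp"]),
            list(a.points["latitude"]) * 2,
            list(a.points["longitude"]) * 2,
        )
        days = daily_summaries(trace, home)
        assert len(days) == 2
        assert days[0].date < days[1].date

    def test_session_gaps_excluded_from_time(self, home, make_trace):
        # two 10-min blocks separated by 8 h: the gap interval contributes
        # nothing to recorded time
        a = trace_from_distances([0.0] * 11)
        b = trace_from_distances([0.0] * 11, start=T0 + pd.Timedelta(hours=8))
        trace = Trace.from_records(
            "t",
            list(a.points["timestamp"]) + list(b.points["timestamp"]),
            list(a.points["latitude"]) * 2,
            list(a.points["longitude"]) * 2,
        )
        (day,) = daily_summaries(trace, home)
        assert day.recorded_seconds == pytest.approx(2 * 600)

    def test_midnight_spanning_interval_split(self, home):
        # fixes at 23:59:30 and 00:00:30 next day, 1 km apart in transit
        ts = [pd.Timestamp("2012-01-02 23:59:30", tz="UTC"),
              pd.Timestamp("2012-01-03 00:00:30", tz="UTC")]
        trace = Trace.from_records(
            "t", ts, [40.0, 40.0 + 1.0 / 111.195], [-70.0, -70.0]
        )
        days = daily_summaries(trace, home)
        assert len(days) == 2
        assert days[0].recorded_seconds == pytest.approx(30)
        assert days[1].recorded_seconds == pytest.approx(30)
        # distance split evenly by time across the two dates
        assert days[0].path_length_km == pytest.approx(days[1].path_length_km)
        assert days[0].path_length_km + days[1].path_length_km == pytest.approx(
            1.0, rel=1e-3
        )

    @settings(derandomize=True, max_examples=40)
    @given(st.lists(st.floats(0, 10), min_size=2, max_size=80))
    def test_day_starting_at_home_path_dominates_max(self, dists):
        """If the day starts at home, the path length is at least the
        maximum home distance (triangle inequality from home)."""
        from conftest import HOME

        trace = trace_from_distances([0.0] + dists)
        (day,) = daily_summaries(trace, HOME)
        assert day.path_length_km >= day.max_home_distance_km - 1e-9


class TestScalarMetrics:
    def test_mean_daily_distance(self, home):
        from lifespace.metrics import DailySummary
        import datetime as dt

        days = [
            DailySummary(dt.date(2012, 1, 2), 4.0, 2.0, 100, 50),
            DailySummary(dt.date(2012, 1, 3), 6.0, 4.0, 100, 50),
        ]
        assert mean_daily_distance(days, "path_length") == pytest.approx(5.0)
        assert mean_daily_distance(days, "max_home_distance") == pytest.approx(3.0)
        assert mean_daily_distance(days[:1], "path_length") == pytest.approx(4.0)
        assert mean_daily_distance(days + days, "path_length") == pytest.approx(5.0)
        assert mean_daily_distance([], "path_length") is None
        with pytest.raises(ValueError):
            mean_daily_distance(days, "nope")

    def test_pct_time_at_home_full(self, home, make_trace):
        days = daily_summaries(make_trace([0.0] * 100), home)
        assert pct_time_at_home(days) == pytest.approx(100.0)

    def test_pct_time_at_home_half(self, home, make_trace):
        # 5 at-home intervals then 5 away intervals (earlier-fix rule)
        trace = make_trace([0.0] * 5 + [2.0] * 6)
        days = daily_summaries(trace, home)
        assert pct_time_at_home(days) == pytest.approx(50.0)

    def test_pct_undefined_without_time(self, home, make_trace):
        assert pct_time_at_home([]) is None
        days = daily_summaries(make_trace([0.0]), home)  # single fix, no interval
        assert pct_time_at_home(days) is None

    def test_trips_per_week(self):
        assert trips_per_week(12, 14) == pytest.approx(6.0)
        assert trips_per_week(0, 10) == 0.0
        assert trips_per_week(1, 7) == pytest.approx(1.0)
        assert trips_per_week(3, 0) is None


def test_metrics_invariant_to_input_order(home):
    rng = np.random.default_rng(2)
    dists = list(rng.uniform(0, 5, 200))
    trace = trace_from_distances(dists)
    days1 = daily_summaries(trace, home)
    shuffled = trace.points.sample(frac=1, random_state=1)
    trace2 = Trace.from_records(
        "t", list(shuffled["timestamp"]), list(shuffled["latitude"]),
        list(shuffled["longitude"]),
    )
    days2 = daily_summaries(trace2, home)
    assert days1 == days2
    assert max_distance(trace, home) == max_distance(trace2, home)
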