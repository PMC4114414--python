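"""Trace I/O, sessionization and metadata invariants."""

import numpy as np
import pandas as pd
import pytest

from lifespace.traces import (
    CsvDialect,
    EmptyTraceError,
    ParticipantMeta,
    Trace,
    TraceFormatError,
    read_metadata_csv,
    read_trace_csv,
    read_trace_gpx,
    recorded_days,
    segment_sessions,
    write_metadata_csv,
    write_trace_csv,
)

from conftest import T0, trace_from_distances


def _write_csv(path, rows, header="participant_id,timestamp,latitude,longitude"):
    path.write_text(header + "\n" + "\n".join(rows) + "\n")


class TestCsv:
    def test_well_formed(self, tmp_path):
        p = tmp_path / "a.csv"
        _write_csv(p, [
            "p1,2012-01-02T09:00:00Z,40.0,-70.0",
            "p1,2012-01-02T09:00:01Z,40.0001,-70.0",
            "p1,2012-01-02T09:00:02Z,40.0002,-70.0",
        ])
        trace, report = read_trace_csv(p)
        assert len(trace) == 3
        assert trace.participant_id == "p1"
        assert report.n_valid == 3 and report.n_bad_coordinate == 0

    def test_bad_rows_dropped_and_counted(self, tmp_path):
        p = tmp_path / "a.csv"
        _write_csv(p, [
            "p1,2012-01-02T09:00:00Z,95.0,-70.0",      # latitude out of range
            "p1,not-a-time,40.0,-70.0",                # bad timestamp
            "p1,2012-01-02T09:00:02Z,40.0,-70.0",
            "p1,2012-01-02T09:00:03Z,40.0,-70.0",
        ])
        trace, report = read_trace_csv(p)
        assert len(trace) == 2
        assert report.n_bad_coordinate == 1
        assert report.n_bad_timestamp == 1

    def test_unsorted_input_sorted(self, tmp_path):
        p = tmp_path / "a.csv"
        _write_csv(p, [
            "p1,2012-01-02T09:00:05Z,40.0,-70.0",
            "p1,2012-01-02T09:00:01Z,40.1,-70.0",
        ])
        trace, _ = read_trace_csv(p)
        assert trace.points["timestamp"].is_monotonic_increasing
        assert trace.points["latitude"].iloc[0] == 40.1

    def test_duplicate_timestamp_keeps_last(self, tmp_path):
        p = tmp_path / "a.csv"
        _write_csv(p, [
            "p1,2012-01-02T09:00:00Z,40.0,-70.0",
            "p1,2012-01-02T09:00:00Z,41.0,-70.0",
        ])
        trace, report = read_trace_csv(p)
        assert len(trace) == 1
        assert trace.points["latitude"].iloc[0] == 41.0
        assert report.n_duplicate_timestamp == 1

    def test_missing_column_raises(self, tmp_path):
        p = tmp_path / "a.csv"
        p.write_text("timestamp,latitude\n2012-01-02T09:00:00Z,40.0\n")
        with pytest.raises(TraceFormatError, match="longitude"):
            read_trace_csv(p)

    def test_zero_valid_rows_raises(self, tmp_path):
        p = tmp_path / "a.csv"
        _write_csv(p, ["p1,bad,999,-70.0"])
        with pytest.raises(EmptyTraceError):
            read_trace_csv(p)

    def test_round_trip(self, tmp_path):
        trace = trace_from_distances([0.0, 0.3, 1.7, 0.1],
                                     step=pd.Timedelta(seconds=13))
        out = tmp_path / "rt.csv"
        write_trace_csv(trace, out)
        back, _ = read_trace_csv(out)
        assert np.array_equal(
            trace.points["timestamp"].to_numpy(), back.points["timestamp"].to_numpy()
        )
        assert np.allclose(trace.points["latitude"], back.points["latitude"], atol=5e-7)
        assert np.allclose(trace.points["longitude"], back.points["longitude"], atol=5e-7)

    def test_custom_dialect(self, tmp_path):
        p = tmp_path / "a.csv"
        p.write_text("when,lat,lon\n02/01/2012 09:00,40.0,-70.0\n")
        d = CsvDialect(timestamp_col="when", latitude_col="lat",
                       longitude_col="lon", timestamp_format="%d/%m/%Y %H:%M")
        trace, _ = read_trace_csv(p, dialect=d, participant_id="x")
        assert len(trace) == 1


_GPX = """<?xml version="1.0"?>
<gpx version="1.1" xmlns="http://www.topografix.com/GPX/1/1">
 <trk><trkseg>
  <trkpt lat="40.0" lon="-70.0"><time>2012-01-02T09:00:05Z</time></trkpt>
  <trkpt lat="40.1" lon="-70.0"><time>2012-01-02T09:00:00Z</time></trkpt>
 </trkseg><trkseg>
  <trkpt lat="40.2" lon="-70.1"><time>2012-01-02T08:59:00Z</time></trkpt>
 </trkseg></trk>
</gpx>
"""


class TestGpx:
    def test_segments_merged_and_sorted(self, tmp_path):
        p = tmp_path / "t.gpx"
        p.write_text(_GPX)
        trace = read_trace_gpx(p)
        assert len(trace) == 3
        assert trace.points["timestamp"].is_monotonic_increasing
        assert trace.points["latitude"].iloc[0] == 40.2

    def test_missing_time_raises(self, tmp_path):
        p = tmp_path / "t.gpx"
        p.write_text(_GPX.replace("<time>2012-01-02T09:00:05Z</time>", ""))
        with pytest.raises(TraceFormatError, match="time"):
            read_trace_gpx(p)


class TestSessions:
    def test_continuous_block_is_one_session(self, make_trace):
        trace = make_trace([0.0] * 600, step=pd.Timedelta(seconds=1))
        sessions = segment_sessions(trace)
        assert len(sessions) == 1
        assert sessions[0].n_points == 600
        assert sessions[0].duration == pd.Timedelta(seconds=599)

    def test_large_gap_splits(self):
        a = trace_from_distances([0.0] * 60, step=pd.Timedelta(minutes=1))
        b = trace_from_distances([0.0] * 60, step=pd.Timedelta(minutes=1),
                                 start=T0 + pd.Timedelta(hours=9))
        trace = Trace.from_records(
            "t",
            list(a.points["timestamp"]) + list(b.points["timestamp"]),
            list(a.points["latitude"]) + list(b.points["latitude"]),
            list(a.points["longitude"]) + list(b.points["longitude"]),
        )
        sessions = segment_sessions(trace)
        assert len(sessions) == 2
        assert sum(s.n_points for s in sessions) == len(trace)

    def test_gap_equal_to_threshold_does_not_split(self, make_trace):
        gap = pd.Timedelta(minutes=5)
        trace = make_trace([0.0, 0.0, 0.0], step=gap)
        assert len(segment_sessions(trace, session_gap=gap)) == 1
        # one second more does split
        trace2 = make_trace([0.0, 0.0], step=gap + pd.Timedelta(seconds=1))
        assert len(segment_sessions(trace2, session_gap=gap)) == 2

    def test_empty_and_validation(self, make_trace):
        assert segment_sessions(make_trace([])) == []
        with pytest.raises(ValueError):
            segment_sessions(make_trace([0.0]), session_gap=pd.Timedelta(0))


class TestRecordedDays:
    def test_distinct_dates(self):
        ts = ["2011-12-01T10:00:00Z", "2011-12-01T22:00:00Z", "2011-12-03T01:00:00Z"]
        trace = Trace.from_records("t", ts, [40.0] * 3, [-70.0] * 3)
        assert recorded_days(trace) == 2

    def test_empty(self, make_trace):
        assert recorded_days(make_trace([])) == 0

    def test_one_point_per_day(self):
        ts = [f"2012-01-{d:02d}T12:00:00Z" for d in range(1, 32)] + [
            f"2012-02-{d:02d}T12:00:00Z" for d in range(1, 10)
        ]
        trace = Trace.from_records("t", ts, [40.0] * 40, [-70.0] * 40)
        assert recorded_days(trace) == 40  # scale of the sparser group

    def test_timezone_matters(self):
        trace = Trace.from_records(
            "t", ["2012-01-02T00:30:00Z", "2012-01-02T01:30:00Z"], [40, 40], [-70, -70]
        )
        assert recorded_days(trace, "UTC") == 1
        assert recorded_days(trace, "America/New_York") == 1  # both prev evening
        trace2 = Trace.from_records(
            "t", ["2012-01-02T04:30:00Z", "2012-01-02T05:30:00Z"], [40, 40], [-70, -70]
        )
        assert recorded_days(trace2, "America/New_York") == 2  # straddles local midnight


class TestMetadata:
    def test_round_trip(self, tmp_path):
        metas = [
            ParticipantMeta("pd01", "PD", age=55, gender="M",
                            updrs_motor_baseline=9, updrs_nonmotor_baseline=2),
            ParticipantMeta("ct01", "control", age=57),
        ]
        p = tmp_path / "meta.csv"
        write_metadata_csv(metas, p)
        back = read_metadata_csv(p)
        assert [m.participant_id for m in back] == ["pd01", "ct01"]
        assert back[0].severity_baseline == 11
        assert back[1].severity_baseline is None

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"group": "other"},
            {"group": "PD", "updrs_motor_baseline": 40},
            {"group": "PD", "updrs_nonmotor_baseline": -1},
        ],
    )
    def test_validation(self, kwargs):
        with pytest.raises(ValueError):
            ParticipantMeta(participant_id="x", **kwargs)
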