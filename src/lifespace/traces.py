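"""GPS trace ingestion, sessionization and participant metadata.

A :class:`Trace` is a participant id plus a chronologically sorted
pandas DataFrame of fixes with columns ``timestamp`` (tz-aware),
``latitude`` and ``longitude`` (decimal degrees WGS84). Recording in the
study protocol this package targets is intermittent — participants ran
the logger for one 4-6 h battery charge per day — so traces are further
segmented into :class:`RecordingSession` blocks wherever the inter-fix
gap exceeds a configurable threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from lxml import etree

DEFAULT_SESSION_GAP = pd.Timedelta(minutes=5)

_TRACE_COLUMNS = ["timestamp", "latitude", "longitude"]


@dataclass
class CsvDialect:
    """Column-name and timestamp configuration for trace CSV files."""

    timestamp_col: str = "timestamp"
    latitude_col: str = "latitude"
    longitude_col: str = "longitude"
    participant_col: str = "participant_id"
    timestamp_format: str | None = None  # None => ISO-8601 via pandas
    timezone: str = "UTC"  # applied to naive timestamps


@dataclass
class LoadReport:
    """Row accounting for one trace load."""

    n_rows: int = 0
    n_valid: int = 0
    n_bad_timestamp: int = 0
    n_bad_coordinate: int = 0
    n_duplicate_timestamp: int = 0

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class Trace:
    """A participant's chronologically sorted GPS time series."""

    participant_id: str
    points: pd.DataFrame  # columns: timestamp, latitude, longitude

    def __post_init__(self) -> None:
        df = self.points
        missing = [c for c in _TRACE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"trace frame missing columns: {missing}")
        self.points = df.loc[:, _TRACE_COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def timestamps(self) -> pd.Series:
        return self.points["timestamp"]

    @classmethod
    def from_records(
        cls,
        participant_id: str,
        timestamps: Sequence,
        latitudes: Sequence[float],
        longitudes: Sequence[float],
    ) -> "Trace":
        """Build a trace from parallel sequences, sorting and de-duplicating."""
        df = pd.DataFrame(
            {
                "timestamp": pd.to_datetime(list(timestamps), utc=True),
                "latitude": np.asarray(latitudes, dtype=float),
                "longitude": np.asarray(longitudes, dtype=float),
            }
        )
        return cls(participant_id, _normalize_frame(df))


def _normalize_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Sort by timestamp (stable) and keep the last record per timestamp."""
    df = df.sort_values("timestamp", kind="stable")
    df = df.drop_duplicates(subset="timestamp", keep="last")
    return df.reset_index(drop=True)


class TraceFormatError(ValueError):
    """Raised when a trace file cannot be interpreted."""


class EmptyTraceError(ValueError):
    """Raised when a trace file yields zero valid fixes."""


def read_trace_csv(
    path: str | Path,
    dialect: CsvDialect | None = None,
    participant_id: str | None = None,
) -> tuple[Trace, LoadReport]:
    """Read a trace CSV, dropping (and counting) malformed rows.

    Rows with unparseable timestamps or out-of-range coordinates are
    rejected, not fatal; the returned :class:`LoadReport` counts them.
    A missing required column raises :class:`TraceFormatError`; a file
    with zero valid rows raises :class:`EmptyTraceError`.
    """
    dialect = dialect or CsvDialect()
    raw = pd.read_csv(path, dtype=str)
    for col in (dialect.timestamp_col, dialect.latitude_col, dialect.longitude_col):
        if col not in raw.columns:
            raise TraceFormatError(f"{path}: missing required column {col!r}")
    report = LoadReport(n_rows=len(raw))

    ts = pd.to_datetime(
        raw[dialect.timestamp_col], format=dialect.timestamp_format, errors="coerce"
    )
    if ts.dt.tz is None:
        ts = ts.dt.tz_localize(dialect.timezone)
    ts = ts.dt.tz_convert("UTC")
    lat = pd.to_numeric(raw[dialect.latitude_col], errors="coerce")
    lon = pd.to_numeric(raw[dialect.longitude_col], errors="coerce")

    bad_ts = ts.isna()
    bad_coord = lat.isna() | lon.isna() | (lat.abs() > 90) | (lon.abs() > 180)
    report.n_bad_timestamp = int(bad_ts.sum())
    report.n_bad_coordinate = int((bad_coord & ~bad_ts).sum())
    keep = ~(bad_ts | bad_coord)

    df = pd.DataFrame(
        {"timestamp": ts[keep], "latitude": lat[keep], "longitude": lon[keep]}
    )
    n_before = len(df)
    df = _normalize_frame(df)
    report.n_duplicate_timestamp = n_before - len(df)
    report.n_valid = len(df)
    if report.n_valid == 0:
        raise EmptyTraceError(f"{path}: no valid GPS fixes")

    if participant_id is None:
        if dialect.participant_col in raw.columns:
            participant_id = str(raw.loc[keep, dialect.participant_col].iloc[0])
        else:
            participant_id = Path(path).stem
    return Trace(participant_id, df), report


def write_trace_csv(trace: Trace, path: str | Path, dialect: CsvDialect | None = None) -> None:
    """Write a trace CSV that round-trips through :func:`read_trace_csv`.

    Timestamps are ISO-8601 UTC at 1 s resolution; coordinates at 6
    decimal places (~0.1 m).
    """
    dialect = dialect or CsvDialect()
    df = pd.DataFrame(
        {
            dialect.participant_col: trace.participant_id,
            dialect.timestamp_col: trace.points["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%SZ"),
            dialect.latitude_col: trace.points["latitude"].map(lambda v: f"{v:.6f}"),
            dialect.longitude_col: trace.points["longitude"].map(lambda v: f"{v:.6f}"),
        }
    )
    df.to_csv(path, index=False)


_GPX_NS = {"gpx": "http://www.topografix.com/GPX/1/1"}


def read_trace_gpx(path: str | Path, participant_id: str | None = None) -> Trace:
    """Read a GPX 1.1 track file; every track point must carry <time>.

    Track points are flattened across tracks and segments, then sorted.
    """
    tree = etree.parse(str(path))
    trkpts = tree.findall(".//gpx:trkpt", _GPX_NS)
    if not trkpts:  # tolerate files written without the namespace
        trkpts = tree.findall(".//trkpt")
    if not trkpts:
        raise TraceFormatError(f"{path}: no track points found")
    times, lats, lons = [], [], []
    for pt in trkpts:
        t = pt.find("gpx:time", _GPX_NS)
        if t is None:
            t = pt.find("time")
        if t is None or not (t.text or "").strip():
            raise TraceFormatError(
                f"{path}: track point without <time>; timestamps are mandatory"
            )
        times.append(t.text.strip())
        lats.append(float(pt.get("lat")))
        lons.append(float(pt.get("lon")))
    if participant_id is None:
        participant_id = Path(path).stem
    return Trace.from_records(participant_id, times, lats, lons)


@dataclass(frozen=True)
class RecordingSession:
    """One contiguous block of recording (inter-fix gaps <= threshold)."""

    start: pd.Timestamp
    end: pd.Timestamp
    n_points: int

    @property
    def duration(self) -> pd.Timedelta:
        return self.end - self.start


def segment_sessions(
    trace: Trace, session_gap: pd.Timedelta = DEFAULT_SESSION_GAP
) -> list[RecordingSession]:
    """Partition the trace into sessions at gaps strictly greater than
    ``session_gap`` (a gap exactly equal to the threshold does not split)."""
    if session_gap <= pd.Timedelta(0):
        raise ValueError("session_gap must be positive")
    ts = trace.points["timestamp"]
    if len(ts) == 0:
        return []
    gaps = ts.diff()
    new_session = gaps > session_gap
    session_id = new_session.cumsum()
    out = []
    for _, grp in ts.groupby(session_id):
        out.append(RecordingSession(start=grp.iloc[0], end=grp.iloc[-1], n_points=len(grp)))
    return out


def recorded_days(trace: Trace, timezone: str = "UTC") -> int:
    """Number of distinct local calendar dates holding at least one fix."""
    ts = trace.points["timestamp"]
    if len(ts) == 0:
        return 0
    return int(ts.dt.tz_convert(timezone).dt.date.nunique())


@dataclass
class ParticipantMeta:
    """Demographics and baseline severity scores for one participant.

    Severity comes from two partial self-report UPDRS subscales: motor
    (13 items, range 0-39) and nonmotor (4 items, range 0-12); higher is
    more impaired.
    """

    participant_id: str
    group: str  # "PD" | "control"
    age: float | None = None
    gender: str | None = None
    updrs_motor_baseline: float | None = None
    updrs_nonmotor_baseline: float | None = None
    updrs_motor_end: float | None = None
    updrs_nonmotor_end: float | None = None

    GROUPS = ("PD", "control")
    MOTOR_MAX = 39.0
    NONMOTOR_MAX = 12.0

    def __post_init__(self) -> None:
        if self.group not in self.GROUPS:
            raise ValueError(f"group must be one of {self.GROUPS}, got {self.group!r}")
        for name, val, hi in (
            ("updrs_motor_baseline", self.updrs_motor_baseline, self.MOTOR_MAX),
            ("updrs_nonmotor_baseline", self.updrs_nonmotor_baseline, self.NONMOTOR_MAX),
            ("updrs_motor_end", self.updrs_motor_end, self.MOTOR_MAX),
            ("updrs_nonmotor_end", self.updrs_nonmotor_end, self.NONMOTOR_MAX),
        ):
            if val is not None and not (0 <= val <= hi):
                raise ValueError(f"{name} must be in [0, {hi}], got {val}")

    @property
    def severity_baseline(self) -> float | None:
        """Summed baseline severity (motor + nonmotor), or None if absent."""
        m, n = self.updrs_motor_baseline, self.updrs_nonmotor_baseline
        if m is None and n is None:
            return None
        return (m or 0.0) + (n or 0.0)


def read_metadata_csv(path: str | Path) -> list[ParticipantMeta]:
    """Read the participant metadata table (one row per participant)."""
    df = pd.read_csv(path)
    metas = []
    for _, row in df.iterrows():
        kwargs = {}
        for field_name in (
            "age",
            "updrs_motor_baseline",
            "updrs_nonmotor_baseline",
            "updrs_motor_end",
            "updrs_nonmotor_end",
        ):
            if field_name in row and pd.notna(row[field_name]):
                kwargs[field_name] = float(row[field_name])
        if "gender" in row and pd.notna(row["gender"]):
            kwargs["gender"] = str(row["gender"])
        metas.append(
            ParticipantMeta(
                participant_id=str(row["participant_id"]),
                group=str(row["group"]),
                **kwargs,
            )
        )
    return metas


def write_metadata_csv(metas: Iterable[ParticipantMeta], path: str | Path) -> None:
    rows = [m.__dict__ for m in metas]
    pd.DataFrame(rows).to_csv(path, index=False)
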