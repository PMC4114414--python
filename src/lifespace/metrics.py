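"""Per-participant Lifespace metrics.

Four summary numbers describe a participant's recorded mobility:

* ``max_distance_km`` — the furthest recorded fix from home;
* ``mean_daily_distance_km`` — mean over recorded days of a per-day
  distance, either the day's maximum distance from home (default) or
  the summed path length (both readings of "daily distance" are
  implemented; the mode used is stamped into every output — see the
  methods note: the path integral of a high-rate noisy GPS stream is
  dominated by positional jitter, while the home-distance reading is
  noise-robust);
* ``pct_time_at_home`` — share of *recorded* time spent within the home
  radius (gaps between recording sessions count toward neither side);
* ``trips_per_week`` — qualifying trips normalized by recorded days,
  ``count * 7 / n_recorded_days``.

Time is accounted in inter-fix intervals within a recording session;
each interval's duration (and its at-home status, taken from the
earlier fix — left-constant interpolation) is attributed to the local
calendar date of its start, with intervals spanning midnight split
proportionally across the two dates. Metrics that are undefined on the
available data (e.g. an empty trace) are explicit ``None``, never 0, so
group statistics can exclude them.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
import datetime as _dt

import numpy as np
import pandas as pd

from .geo import EarthModel, GeoPoint, haversine_km_arrays
from .home import HomeRadiusPolicy, at_home_mask
from .traces import DEFAULT_SESSION_GAP, Trace

DAILY_DISTANCE_MODES = ("path_length", "max_home_distance")


@dataclass(frozen=True)
class DailySummary:
    date: _dt.date
    path_length_km: float
    max_home_distance_km: float
    recorded_seconds: float
    seconds_at_home: float


@dataclass(frozen=True)
class LifespaceMetrics:
    participant_id: str
    max_distance_km: float | None
    mean_daily_distance_km: float | None
    pct_time_at_home: float | None
    trips_per_week: float | None
    n_recorded_days: int
    daily_distance_mode: str

    def to_dict(self) -> dict:
        return asdict(self)


def max_distance(
    trace: Trace, home: GeoPoint, earth: EarthModel = EarthModel()
) -> float | None:
    """Furthest recorded distance from home, km; None for an empty trace."""
    if len(trace) == 0:
        return None
    d = haversine_km_arrays(
        trace.points["latitude"].to_numpy(),
        trace.points["longitude"].to_numpy(),
        home.latitude_deg,
        home.longitude_deg,
        earth,
    )
    return float(np.max(d))


def _intervals(
    trace: Trace,
    home: GeoPoint,
    policy: HomeRadiusPolicy,
    session_gap: pd.Timedelta,
    earth: EarthModel,
) -> pd.DataFrame:
    """Inter-fix intervals within sessions: start, seconds, dist_km, at_home."""
    df = trace.points
    ts = df["timestamp"]
    gap_s = ts.diff().dt.total_seconds().to_numpy()[1:]
    lat = df["latitude"].to_numpy()
    lon = df["longitude"].to_numpy()
    seg_km = np.asarray(
        haversine_km_arrays(lat[:-1], lon[:-1], lat[1:], lon[1:], earth)
    )
    mask = at_home_mask(trace, home, policy, earth)[:-1]
    in_session = gap_s <= session_gap.total_seconds()
    out = pd.DataFrame(
        {
            "start": ts.to_numpy()[:-1],
            "seconds": gap_s,
            "dist_km": seg_km,
            "at_home": mask,
        }
    )
    return out[in_session].reset_index(drop=True)


def daily_summaries(
    trace: Trace,
    home: GeoPoint,
    policy: HomeRadiusPolicy = HomeRadiusPolicy(),
    session_gap: pd.Timedelta = DEFAULT_SESSION_GAP,
    timezone: str = "UTC",
    earth: EarthModel = EarthModel(),
) -> list[DailySummary]:
    """One summary per recorded local calendar date.

    Intervals spanning local midnight are split proportionally by time,
    crediting each date its share of duration and segment distance.
    """
    if len(trace) == 0:
        return []
    iv = _intervals(trace, home, policy, session_gap, earth)

    rows = []
    if len(iv):
        start = pd.DatetimeIndex(iv["start"]).tz_convert(timezone)
        end = start + pd.to_timedelta(iv["seconds"].to_numpy(), unit="s")
        same_day = start.date == end.date
        for s, sec, km, ah in zip(
            start[same_day],
            iv.loc[same_day, "seconds"],
            iv.loc[same_day, "dist_km"],
            iv.loc[same_day, "at_home"],
        ):
            rows.append((s.date(), sec, km, ah))
        # midnight-spanning intervals: walk day by day (rare, small)
        for s, e, km, ah in zip(
            start[~same_day], end[~same_day], iv.loc[~same_day, "dist_km"],
            iv.loc[~same_day, "at_home"],
        ):
            total = (e - s).total_seconds()
            cur = s
            while cur < e:
                nxt_midnight = (cur + pd.Timedelta(days=1)).normalize()
                stop = min(nxt_midnight, e)
                part = (stop - cur).total_seconds()
                rows.append((cur.date(), part, km * part / total, ah))
                cur = stop

    iv_by_day: dict[_dt.date, list] = {}
    for date, sec, km, ah in rows:
        iv_by_day.setdefault(date, []).append((sec, km, ah))

    # per-fix home distances for the daily maximum (fix-based, not interval)
    local = trace.points["timestamp"].dt.tz_convert(timezone)
    fix_date = local.dt.date
    home_d = np.asarray(
        haversine_km_arrays(
            trace.points["latitude"].to_numpy(),
            trace.points["longitude"].to_numpy(),
            home.latitude_deg,
            home.longitude_deg,
            earth,
        )
    )
    max_by_day = pd.Series(home_d).groupby(fix_date.to_numpy()).max()

    out = []
    for date in sorted(max_by_day.index):
        day_iv = iv_by_day.get(date, [])
        rec = float(sum(sec for sec, _, _ in day_iv))
        ah_sec = float(sum(sec for sec, _, ah in day_iv if ah))
        path = float(sum(km for _, km, _ in day_iv))
        out.append(
            DailySummary(
                date=date,
                path_length_km=path,
                max_home_distance_km=float(max_by_day.loc[date]),
                recorded_seconds=rec,
                seconds_at_home=ah_sec,
            )
        )
    return out


def mean_daily_distance(
    summaries: list[DailySummary], mode: str = "max_home_distance"
) -> float | None:
    """Mean over recorded days of the chosen per-day distance, km."""
    if mode not in DAILY_DISTANCE_MODES:
        raise ValueError(f"mode must be one of {DAILY_DISTANCE_MODES}, got {mode!r}")
    if not summaries:
        return None
    field = "path_length_km" if mode == "path_length" else "max_home_distance_km"
    return float(np.mean([getattr(s, field) for s in summaries]))


def pct_time_at_home(summaries: list[DailySummary]) -> float | None:
    """Percent of recorded interval-time spent at home; None if no time."""
    rec = sum(s.recorded_seconds for s in summaries)
    if rec <= 0:
        return None
    return 100.0 * sum(s.seconds_at_home for s in summaries) / rec


def trips_per_week(trip_count: int, n_recorded_days: int) -> float | None:
    """Qualifying trips scaled to a 7-day week of recorded days."""
    if n_recorded_days < 1:
        return None
    return trip_count * 7.0 / n_recorded_days
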