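"""Trip detection with a two-state finite-state machine.

The machine has two states — subject at home (SH) and subject not at
home (SNH) — and steps through the fixes in time order. SH -> SNH fires
at the first fix more than ``radius_km`` from home (its timestamp is the
departure); SNH -> SH fires at the first fix back within the radius (its
timestamp is the return). Each closed SH -> SNH -> SH cycle is one
:class:`Trip`. Excursions shorter than ``min_trip_duration`` are kept
but flagged non-qualifying: short blips are usually GPS noise near the
radius, not real trips.

Because the machine has no hysteresis, its output is exactly the maximal
runs of the at-home mask, which is how the production path computes it
(vectorized); the per-fix state scan is retained in the test suite as an
independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .geo import EarthModel, GeoPoint, haversine_km_arrays
from .traces import Trace


class FsmState(Enum):
    SH = "at_home"
    SNH = "not_at_home"


@dataclass(frozen=True)
class FsmConfig:
    radius_km: float = 0.5
    min_trip_duration_min: float = 15.0
    count_open_trips: bool = False

    def __post_init__(self) -> None:
        if self.radius_km <= 0:
            raise ValueError("radius_km must be positive")
        if self.min_trip_duration_min < 0:
            raise ValueError("min_trip_duration_min must be >= 0")


@dataclass(frozen=True)
class Trip:
    """One excursion beyond the home radius.

    ``depart_time`` is the first fix observed outside the radius;
    ``return_time`` the first fix back inside, or None if the trace ends
    away from home (open end). ``open_start`` marks a trace that already
    begins away from home, where no departure was observed.
    """

    depart_time: pd.Timestamp
    return_time: pd.Timestamp | None
    duration_min: float
    max_distance_km: float
    qualifying: bool
    open_start: bool = False
    open_end: bool = False

    @property
    def closed(self) -> bool:
        return not (self.open_start or self.open_end)


def detect_trips(
    trace: Trace,
    home: GeoPoint,
    cfg: FsmConfig = FsmConfig(),
    earth: EarthModel = EarthModel(),
) -> list[Trip]:
    """Run the two-state machine over the trace and list its trips.

    Open-start and open-end excursions are emitted with their flags set;
    whether they count is the caller's concern (see
    :func:`count_qualifying_trips`).
    """
    n = len(trace)
    if n == 0:
        return []
    ts = trace.points["timestamp"].to_numpy()
    dist = np.asarray(
        haversine_km_arrays(
            trace.points["latitude"].to_numpy(),
            trace.points["longitude"].to_numpy(),
            home.latitude_deg,
            home.longitude_deg,
            earth,
        )
    )
    away = dist > cfg.radius_km  # boundary fix (== radius) is at home

    trips: list[Trip] = []
    # maximal runs of `away`: starts where away rises, ends where it falls
    change = np.diff(away.astype(np.int8))
    starts = np.flatnonzero(change == 1) + 1
    ends = np.flatnonzero(change == -1) + 1  # index of first at-home fix after run
    if away[0]:
        starts = np.concatenate(([0], starts))
    for k, s in enumerate(starts):
        open_start = s == 0 and bool(away[0])
        if k < len(ends):
            e = int(ends[k])  # first fix back within radius
            return_time = pd.Timestamp(ts[e])
            open_end = False
            last = e
        else:
            return_time = None
            open_end = True
            last = n - 1
        depart_time = pd.Timestamp(ts[s])
        end_time = return_time if return_time is not None else pd.Timestamp(ts[last])
        duration_min = (end_time - depart_time).total_seconds() / 60.0
        max_distance_km = float(dist[s : last + 1].max())
        trips.append(
            Trip(
                depart_time=depart_time,
                return_time=return_time,
                duration_min=duration_min,
                max_distance_km=max_distance_km,
                qualifying=duration_min >= cfg.min_trip_duration_min,
                open_start=open_start,
                open_end=open_end,
            )
        )
    return trips


def count_qualifying_trips(trips: list[Trip], cfg: FsmConfig = FsmConfig()) -> int:
    """Number of trips that count toward the trips-per-week metric:
    closed qualifying trips, plus open ones if so configured."""
    return sum(
        1
        for t in trips
        if t.qualifying and (t.closed or cfg.count_open_trips)
    )


def trips_to_frame(trips: list[Trip]) -> pd.DataFrame:
    """Trip list as a DataFrame for CSV export."""
    return pd.DataFrame(
        [
            {
                "depart_time": t.depart_time,
                "return_time": t.return_time,
                "duration_min": t.duration_min,
                "max_distance_km": t.max_distance_km,
                "qualifying": t.qualifying,
                "open_start": t.open_start,
                "open_end": t.open_end,
            }
            for t in trips
        ],
        columns=[
            "depart_time",
            "return_time",
            "duration_min",
            "max_distance_km",
            "qualifying",
            "open_start",
            "open_end",
        ],
    )
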