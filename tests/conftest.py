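"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from lifespace.fsm import FsmConfig, Trip
from lifespace.geo import EARTH_RADIUS_KM, GeoPoint, haversine_km
from lifespace.traces import Trace

KM_PER_DEG = math.pi / 180.0 * EARTH_RADIUS_KM

HOME = GeoPoint(40.0, -70.0)
T0 = pd.Timestamp("2012-01-02 09:00:00", tz="UTC")


def trace_from_distances(
    dists_km, step=pd.Timedelta(minutes=1), home=HOME, start=T0,
    participant_id="t",
):
    """Trace whose fix i sits ``dists_km[i]`` due north of home."""
    ts = [start + i * step for i in range(len(dists_km))]
    lats = [home.latitude_deg + d / KM_PER_DEG for d in dists_km]
    lons = [home.longitude_deg] * len(dists_km)
    return Trace.from_records(participant_id, ts, lats, lons)


@pytest.fixture
def home():
    return HOME


@pytest.fixture
def make_trace():
    return trace_from_distances


def brute_force_trips(trace: Trace, home: GeoPoint, cfg: FsmConfig) -> list[Trip]:
    """Independent per-fix two-state scan, materializing the state at
    every point; the oracle the vectorized detector is checked against."""
    n = len(trace)
    if n == 0:
        return []
    pts = trace.points
    dists = [
        haversine_km(GeoPoint(la, lo), home)
        for la, lo in zip(pts["latitude"], pts["longitude"])
    ]
    ts = list(pts["timestamp"])
    trips = []
    if dists[0] > cfg.radius_km:
        state = "SNH"
        depart, maxd, open_start = ts[0], dists[0], True
    else:
        state = "SH"
        depart, maxd, open_start = None, 0.0, False
    for i in range(1, n):
        d = dists[i]
        if state == "SH":
            if d > cfg.radius_km:
                state, depart, maxd, open_start = "SNH", ts[i], d, False
        else:
            maxd = max(maxd, d)
            if d <= cfg.radius_km:
                dur = (ts[i] - depart).total_seconds() / 60.0
                trips.append(
                    Trip(depart, ts[i], dur, maxd,
                         dur >= cfg.min_trip_duration_min,
                         open_start=open_start, open_end=False)
                )
                state = "SH"
    if state == "SNH":
        dur = (ts[-1] - depart).total_seconds() / 60.0
        trips.append(
            Trip(depart, None, dur, maxd, dur >= cfg.min_trip_duration_min,
                 open_start=open_start, open_end=True)
        )
    return trips


def random_boundary_trace(rng: np.random.Generator, max_points=1000,
                          home=HOME) -> Trace:
    """Random trace whose distances straddle the 0.5 km radius, built to
    exercise FSM transitions (runs of in/out with jitter near the edge)."""
    n = int(rng.integers(1, max_points + 1))
    # piecewise-constant regime (in/out) with noisy distance
    regime = np.cumsum(rng.random(n) < 0.05) % 2
    base = np.where(regime == 0, 0.2, 1.5)
    dist = np.abs(base + rng.normal(0, 0.4, n))  # crosses 0.5 often
    step = pd.Timedelta(seconds=int(rng.integers(5, 120)))
    return trace_from_distances(dist, step=step, home=home)
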