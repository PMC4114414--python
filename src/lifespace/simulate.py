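"""Synthetic GPS traces with known ground truth.

The generator emulates the recording protocol the analysis assumes:
participants carry a logging phone for one battery charge (4-6 h) per
day over weeks, dwelling at a fixed home and making out-and-back trips
into the community. Each non-skipped day gets one recording window;
within it the subject sits at home except during trips — straight-line
travel at a sampled speed to a destination at a sampled bearing and
distance, a dwell there, and the return leg. Fixes are sampled at a
fixed interval and perturbed with isotropic Gaussian noise (default
sigma 10 m, typical outdoor smartphone GPS accuracy), converted from
meters to degrees in the local tangent plane at the home latitude.

Trip destinations are log-normal in distance with a floor of 0.75 km:
under a 500 m home radius, nearer errands are indistinguishable from
home, so the generator only plants trips the detector could in
principle see. Alongside the trace the simulator emits a
:class:`SyntheticTruth` — true home, trip log, recording windows, and
noise-free seconds-at-home — for recovery testing.

Everything is driven by one integer seed; identical config and seed
give identical output.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .geo import EARTH_RADIUS_KM, GeoPoint
from .traces import ParticipantMeta, Trace

_KM_PER_DEG_LAT = math.pi / 180.0 * EARTH_RADIUS_KM  # ~111.195


@dataclass(frozen=True)
class SimulationConfig:
    """Study-protocol parameters for one simulated participant."""

    seed: int = 0
    n_days: int = 40
    home: GeoPoint = GeoPoint(44.80, -68.77)  # semirural New England
    start_date: _dt.date = _dt.date(2012, 1, 2)
    window_start_hour: tuple[float, float] = (8.0, 14.0)
    window_duration_h: tuple[float, float] = (4.0, 6.0)  # one charge cycle
    sample_interval_s: int = 10  # 1 reproduces the study's 1 Hz stream
    trips_per_day: float = 0.867  # Poisson mean; ~6 trips/week
    deterministic_trip_count: int | None = None  # exactly N trips/day if set
    trip_distance_logmedian_km: float = 4.0
    trip_distance_logsigma: float = 0.6
    trip_distance_floor_km: float = 0.75
    trip_dwell_min: tuple[float, float] = (20.0, 90.0)
    travel_speed_kmh: tuple[float, float] = (20.0, 50.0)
    gps_noise_m: float = 10.0
    p_day_skipped: float = 0.1
    min_home_gap_min: float = 20.0  # home dwell separating trips/window edges
    max_trip_retries: int = 5

    def __post_init__(self) -> None:
        if self.sample_interval_s < 1:
            raise ValueError("sample_interval_s must be >= 1")
        if self.gps_noise_m < 0:
            raise ValueError("gps_noise_m must be >= 0")
        if not 0 <= self.p_day_skipped <= 1:
            raise ValueError("p_day_skipped must be a probability")


@dataclass(frozen=True)
class TruthTrip:
    depart: pd.Timestamp
    ret: pd.Timestamp
    destination_distance_km: float


@dataclass
class SyntheticTruth:
    """Ground truth emitted next to a simulated trace."""

    true_home: GeoPoint
    trips: list[TruthTrip]
    windows: dict[_dt.date, tuple[pd.Timestamp, pd.Timestamp]]
    seconds_at_home: dict[_dt.date, float]  # noise-free, 500 m radius
    recorded_seconds: dict[_dt.date, float]
    n_dropped_trips: int = 0

    @property
    def n_trips(self) -> int:
        return len(self.trips)

    @property
    def pct_time_at_home(self) -> float:
        rec = sum(self.recorded_seconds.values())
        return 100.0 * sum(self.seconds_at_home.values()) / rec if rec else float("nan")

    def to_dict(self) -> dict:
        return {
            "true_home": [self.true_home.latitude_deg, self.true_home.longitude_deg],
            "trips": [
                {"depart": str(t.depart), "return": str(t.ret),
                 "destination_distance_km": t.destination_distance_km}
                for t in self.trips
            ],
            "windows": {
                str(d): [str(a), str(b)] for d, (a, b) in self.windows.items()
            },
            "seconds_at_home": {str(d): v for d, v in self.seconds_at_home.items()},
            "recorded_seconds": {str(d): v for d, v in self.recorded_seconds.items()},
            "n_dropped_trips": self.n_dropped_trips,
        }


def _sample_trip(rng: np.random.Generator, cfg: SimulationConfig):
    dist = max(
        float(rng.lognormal(math.log(cfg.trip_distance_logmedian_km),
                            cfg.trip_distance_logsigma)),
        cfg.trip_distance_floor_km,
    )
    speed = float(rng.uniform(*cfg.travel_speed_kmh))
    dwell_min = float(rng.uniform(*cfg.trip_dwell_min))
    bearing = float(rng.uniform(0, 2 * math.pi))
    travel_min = dist / speed * 60.0
    total_min = 2 * travel_min + dwell_min
    return dist, speed, dwell_min, bearing, travel_min, total_min


def simulate_participant(cfg: SimulationConfig) -> tuple[Trace, SyntheticTruth]:
    """Simulate one participant's trace plus its ground truth."""
    rng = np.random.default_rng(cfg.seed)
    home = cfg.home
    cos_lat = math.cos(math.radians(home.latitude_deg))

    all_ts: list[np.ndarray] = []
    all_lat: list[np.ndarray] = []
    all_lon: list[np.ndarray] = []
    truth = SyntheticTruth(true_home=home, trips=[], windows={},
                           seconds_at_home={}, recorded_seconds={})

    for day_idx in range(cfg.n_days):
        date = cfg.start_date + _dt.timedelta(days=day_idx)
        day0 = pd.Timestamp(date, tz="UTC")
        if rng.random() < cfg.p_day_skipped:
            continue
        w_start = day0 + pd.Timedelta(hours=float(rng.uniform(*cfg.window_start_hour)))
        w_end = w_start + pd.Timedelta(hours=float(rng.uniform(*cfg.window_duration_h)))
        truth.windows[date] = (w_start, w_end)

        if cfg.deterministic_trip_count is not None:
            n_trips = cfg.deterministic_trip_count
        else:
            n_trips = int(rng.poisson(cfg.trips_per_day))

        gap = pd.Timedelta(minutes=cfg.min_home_gap_min)
        cursor = w_start
        day_trips = []  # (depart, dist, speed, dwell_min, bearing, travel_min)
        for _ in range(n_trips):
            placed = False
            for _try in range(cfg.max_trip_retries):
                dist, speed, dwell_min, bearing, travel_min, total_min = \
                    _sample_trip(rng, cfg)
                jitter = pd.Timedelta(minutes=float(rng.uniform(0, 30)))
                depart = cursor + gap + jitter
                ret = depart + pd.Timedelta(minutes=total_min)
                if ret + gap <= w_end:
                    day_trips.append((depart, dist, speed, dwell_min, bearing,
                                      travel_min))
                    truth.trips.append(TruthTrip(depart, ret, dist))
                    cursor = ret
                    placed = True
                    break
            if not placed:
                truth.n_dropped_trips += 1

        # sample the day's window
        n_samples = int((w_end - w_start).total_seconds() // cfg.sample_interval_s) + 1
        t_off = np.arange(n_samples) * float(cfg.sample_interval_s)
        t_abs = w_start.value / 1e9 + t_off  # epoch seconds
        dist_from_home = np.zeros(n_samples)  # km, noise-free
        bearing_arr = np.zeros(n_samples)
        for depart, dist, speed, dwell_min, bearing, travel_min in day_trips:
            d0 = (depart - w_start).total_seconds()
            t_out = travel_min * 60.0
            t_dwell = dwell_min * 60.0
            rel = t_off - d0
            out = (rel >= 0) & (rel < t_out)
            dwell = (rel >= t_out) & (rel < t_out + t_dwell)
            back = (rel >= t_out + t_dwell) & (rel < 2 * t_out + t_dwell)
            dist_from_home[out] = speed / 3600.0 * rel[out]
            dist_from_home[dwell] = dist
            dist_from_home[back] = np.maximum(
                dist - speed / 3600.0 * (rel[back] - t_out - t_dwell), 0.0
            )
            bearing_arr[out | dwell | back] = bearing

        dlat = dist_from_home * np.cos(bearing_arr) / _KM_PER_DEG_LAT
        dlon = dist_from_home * np.sin(bearing_arr) / (_KM_PER_DEG_LAT * cos_lat)
        lat = home.latitude_deg + dlat
        lon = home.longitude_deg + dlon
        if cfg.gps_noise_m > 0:
            sig_deg_lat = cfg.gps_noise_m / 1000.0 / _KM_PER_DEG_LAT
            lat = lat + rng.normal(0, sig_deg_lat, n_samples)
            lon = lon + rng.normal(0, sig_deg_lat / cos_lat, n_samples)

        # noise-free interval truth, same left-constant convention as the
        # metrics: each non-final sample contributes sample_interval seconds
        at_home_true = dist_from_home <= 0.5
        sec = float(cfg.sample_interval_s)
        truth.recorded_seconds[date] = sec * max(n_samples - 1, 0)
        truth.seconds_at_home[date] = sec * float(at_home_true[:-1].sum())

        all_ts.append(t_abs)
        all_lat.append(lat)
        all_lon.append(lon)

    if all_ts:
        ts = pd.to_datetime(np.concatenate(all_ts), unit="s", utc=True)
        points = pd.DataFrame(
            {
                "timestamp": ts.round("ms"),
                "latitude": np.concatenate(all_lat),
                "longitude": np.concatenate(all_lon),
            }
        )
    else:
        points = pd.DataFrame(columns=["timestamp", "latitude", "longitude"])
    trace = Trace(participant_id=f"sim-{cfg.seed}", points=points)
    return trace, truth


PD_DEFAULTS = SimulationConfig(n_days=40, trips_per_day=6.07 / 7.0)
CONTROL_DEFAULTS = SimulationConfig(n_days=22, trips_per_day=3.97 / 7.0)


@dataclass
class CohortSim:
    traces: dict[str, Trace]
    truths: dict[str, SyntheticTruth]
    metas: list[ParticipantMeta]


def simulate_cohort(
    n_pd: int = 9,
    n_control: int = 7,
    cfg_pd: SimulationConfig = PD_DEFAULTS,
    cfg_control: SimulationConfig = CONTROL_DEFAULTS,
    seed: int = 0,
) -> CohortSim:
    """Simulate a two-group cohort with a planted severity gradient.

    Child seeds derive deterministically from the master seed. PD
    participants' trip rates fan out around the group rate and their
    baseline severity scores decrease monotonically with trip rate, so
    severity-ordered analyses have a planted signal (more symptoms,
    fewer trips). Homes are scattered so participants do not share a
    location.
    """
    if n_pd < 1 or n_control < 1:
        raise ValueError("group sizes must be positive")
    master = np.random.default_rng(seed)
    child_seeds = master.integers(0, 2**31 - 1, size=n_pd + n_control)

    traces: dict[str, Trace] = {}
    truths: dict[str, SyntheticTruth] = {}
    metas: list[ParticipantMeta] = []

    # PD: trip rate multiplier spans x0.5 .. x1.6; severity maps inversely
    rate_mult = np.geomspace(0.5, 1.6, n_pd)
    motor = np.round(np.linspace(23, 5, n_pd)).astype(int)     # high sev <-> low rate
    nonmotor = np.round(np.linspace(6, 0, n_pd)).astype(int)

    for i in range(n_pd):
        pid = f"pd{i + 1:02d}"
        home = GeoPoint(
            cfg_pd.home.latitude_deg + float(master.uniform(-0.5, 0.5)),
            cfg_pd.home.longitude_deg + float(master.uniform(-0.5, 0.5)),
        )
        cfg = replace(
            cfg_pd,
            seed=int(child_seeds[i]),
            home=home,
            trips_per_day=cfg_pd.trips_per_day * float(rate_mult[i]),
        )
        trace, truth = simulate_participant(cfg)
        trace = Trace(pid, trace.points)
        traces[pid], truths[pid] = trace, truth
        metas.append(
            ParticipantMeta(
                participant_id=pid, group="PD",
                age=float(np.round(master.normal(58, 7))), gender="M" if master.random() < 0.78 else "F",
                updrs_motor_baseline=float(motor[i]),
                updrs_nonmotor_baseline=float(nonmotor[i]),
            )
        )

    for j in range(n_control):
        pid = f"ct{j + 1:02d}"
        home = GeoPoint(
            cfg_control.home.latitude_deg + float(master.uniform(-0.5, 0.5)),
            cfg_control.home.longitude_deg + float(master.uniform(-0.5, 0.5)),
        )
        cfg = replace(cfg_control, seed=int(child_seeds[n_pd + j]), home=home)
        trace, truth = simulate_participant(cfg)
        trace = Trace(pid, trace.points)
        traces[pid], truths[pid] = trace, truth
        metas.append(
            ParticipantMeta(
                participant_id=pid, group="control",
                age=float(np.round(master.normal(60, 9))), gender="M" if master.random() < 0.71 else "F",
            )
        )
    return CohortSim(traces=traces, truths=truths, metas=metas)
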