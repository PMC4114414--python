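"""Model/Results interface tying the pipeline stages together.

:class:`LifespaceModel` wraps one participant's GPS trace and a
:class:`~lifespace.config.StudyConfig`; :meth:`~LifespaceModel.fit`
runs sessionization, home inference, trip detection and metric
computation and returns a :class:`LifespaceResults` carrying the
estimates, per-day summaries and diagnostics, with ``summary()`` for a
human-readable report and plotting helpers built on the
privacy-preserving visualization layer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import pandas as pd

from . import fsm, metrics as metrics_mod, stats, viz
from .config import StudyConfig
from .home import HomeEstimate, HomeRadiusPolicy, infer_home
from .traces import RecordingSession, Trace, recorded_days, segment_sessions


class LifespaceModel:
    """Per-participant Lifespace analysis.

    Parameters
    ----------
    trace : Trace
        Chronologically sorted GPS trace.
    config : StudyConfig, optional
        Analysis constants (home radius, trip filter, timezone, ...).
    """

    def __init__(self, trace: Trace, config: StudyConfig | None = None):
        self.trace = trace
        self.config = config or StudyConfig()

    @classmethod
    def from_csv(cls, path, config: StudyConfig | None = None, dialect=None):
        from .traces import read_trace_csv

        trace, _ = read_trace_csv(path, dialect=dialect)
        return cls(trace, config)

    def fit(self) -> "LifespaceResults":
        """Run the full per-participant pipeline."""
        cfg = self.config
        trace = self.trace
        if len(trace) == 0:
            return LifespaceResults(
                model=self,
                sessions=[],
                home_estimate=None,
                trips=[],
                daily=[],
                metrics=metrics_mod.LifespaceMetrics(
                    participant_id=trace.participant_id,
                    max_distance_km=None,
                    mean_daily_distance_km=None,
                    pct_time_at_home=None,
                    trips_per_week=None,
                    n_recorded_days=0,
                    daily_distance_mode=cfg.daily_distance_mode,
                ),
            )
        sessions = segment_sessions(trace, cfg.session_gap)
        home_est = infer_home(trace, cfg.cell_size_deg)
        policy = HomeRadiusPolicy(cfg.radius_km)
        fsm_cfg = fsm.FsmConfig(
            radius_km=cfg.radius_km,
            min_trip_duration_min=cfg.min_trip_duration_min,
            count_open_trips=cfg.count_open_trips,
        )
        trips = fsm.detect_trips(trace, home_est.home, fsm_cfg)
        daily = metrics_mod.daily_summaries(
            trace, home_est.home, policy, cfg.session_gap, cfg.timezone
        )
        n_days = recorded_days(trace, cfg.timezone)
        n_trips = fsm.count_qualifying_trips(trips, fsm_cfg)
        lsm = metrics_mod.LifespaceMetrics(
            participant_id=trace.participant_id,
            max_distance_km=metrics_mod.max_distance(trace, home_est.home),
            mean_daily_distance_km=metrics_mod.mean_daily_distance(
                daily, cfg.daily_distance_mode
            ),
            pct_time_at_home=metrics_mod.pct_time_at_home(daily),
            trips_per_week=metrics_mod.trips_per_week(n_trips, n_days),
            n_recorded_days=n_days,
            daily_distance_mode=cfg.daily_distance_mode,
        )
        return LifespaceResults(
            model=self,
            sessions=sessions,
            home_estimate=home_est,
            trips=trips,
            daily=daily,
            metrics=lsm,
        )


@dataclass
class LifespaceResults:
    """Fitted per-participant results."""

    model: LifespaceModel
    sessions: list[RecordingSession]
    home_estimate: HomeEstimate | None
    trips: list[fsm.Trip]
    daily: list[metrics_mod.DailySummary]
    metrics: metrics_mod.LifespaceMetrics

    @property
    def participant_id(self) -> str:
        return self.model.trace.participant_id

    @property
    def n_qualifying_trips(self) -> int:
        cfg = self.model.config
        return fsm.count_qualifying_trips(
            self.trips,
            fsm.FsmConfig(
                radius_km=cfg.radius_km,
                min_trip_duration_min=cfg.min_trip_duration_min,
                count_open_trips=cfg.count_open_trips,
            ),
        )

    def summary(self) -> str:
        m = self.metrics

        def _f(v, unit=""):
            return "NA" if v is None else f"{v:.2f}{unit}"

        lines = [
            f"Lifespace results — participant {self.participant_id}",
            f"  config hash            {self.model.config.config_hash()}",
            f"  fixes / sessions       {len(self.model.trace)} / {len(self.sessions)}",
            f"  recorded days          {m.n_recorded_days}",
            f"  trips (qualifying)     {len(self.trips)} ({self.n_qualifying_trips})",
            f"  max distance from home {_f(m.max_distance_km, ' km')}",
            f"  mean daily distance    {_f(m.mean_daily_distance_km, ' km')}"
            f"  [{m.daily_distance_mode}]",
            f"  % recorded time at home {_f(m.pct_time_at_home, ' %')}",
            f"  trips per week         {_f(m.trips_per_week)}",
        ]
        return "\n".join(lines)

    # ------------------------------------------------------------- exports

    def metrics_row(self) -> dict:
        return self.metrics.to_dict()

    def to_json(self, path, include_home: bool = False) -> None:
        """Write the result bundle as JSON. Absolute home coordinates are
        withheld unless ``include_home`` (privacy default)."""
        bundle = {
            "participant_id": self.participant_id,
            "config": self.model.config.to_dict(),
            "config_hash": self.model.config.config_hash(),
            "metrics": self.metrics.to_dict(),
            "n_sessions": len(self.sessions),
            "n_trips": len(self.trips),
            "n_qualifying_trips": self.n_qualifying_trips,
        }
        if include_home and self.home_estimate is not None:
            bundle["home_estimate"] = self.home_estimate.to_dict()
        with open(path, "w") as fh:
            json.dump(bundle, fh, indent=2)

    def trips_frame(self) -> pd.DataFrame:
        return fsm.trips_to_frame(self.trips)

    # ------------------------------------------------------------ plotting

    def plot_scatter(self, ax=None):
        return viz.render_scatter(self.model.trace, ax=ax)

    def plot_heatmap(self, period=None, ax=None):
        grid = viz.heat_grid(
            self.model.trace,
            period=period,
            n_bins=self.model.config.heatmap_bins,
            session_gap=self.model.config.session_gap,
        )
        return viz.render_heatmap(grid, ax=ax)

    def plot_timeline(self, ax=None):
        bars = viz.recording_timeline(self.sessions, self.model.config.timezone)
        return viz.render_timeline(bars, ax=ax)


def fit_cohort(
    traces: dict[str, Trace], config: StudyConfig | None = None
) -> dict[str, LifespaceResults]:
    """Fit every participant; returns results keyed by participant id."""
    return {pid: LifespaceModel(t, config).fit() for pid, t in traces.items()}


def cohort_metrics_frame(
    results: dict[str, LifespaceResults], metas=None
) -> pd.DataFrame:
    """Study-wide metrics table, one row per participant, with group
    labels joined from metadata when provided."""
    rows = [r.metrics_row() for r in results.values()]
    df = pd.DataFrame(rows)
    if metas is not None:
        meta_df = pd.DataFrame(
            [
                {
                    "participant_id": m.participant_id,
                    "group": m.group,
                    "severity_baseline": m.severity_baseline,
                }
                for m in metas
            ]
        )
        df = df.merge(meta_df, on="participant_id", how="left")
    return df.sort_values("participant_id").reset_index(drop=True)


def compare_cohort(
    metrics_df: pd.DataFrame, metas=None
) -> tuple[stats.GroupComparison, pd.DataFrame]:
    """Group comparison plus the severity-ordered PD table."""
    comparison = stats.compare_groups(metrics_df)
    sev = pd.DataFrame()
    if metas is not None:
        by_id = {}
        for _, row in metrics_df.iterrows():
            by_id[row["participant_id"]] = metrics_mod.LifespaceMetrics(
                participant_id=row["participant_id"],
                max_distance_km=row.get("max_distance_km"),
                mean_daily_distance_km=row.get("mean_daily_distance_km"),
                pct_time_at_home=row.get("pct_time_at_home"),
                trips_per_week=row.get("trips_per_week"),
                n_recorded_days=int(row.get("n_recorded_days", 0)),
                daily_distance_mode=row.get("daily_distance_mode", "path_length"),
            )
        sev = stats.severity_order(metas, by_id)
    return comparison, sev
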