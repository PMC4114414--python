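"""Privacy-preserving visualization data: scatter, dwell heatmaps,
recording timelines.

Nothing in this module emits an absolute coordinate. Scatter data are
centroid-subtracted degrees; heat grids live in the same mean-subtracted
frame and hold *dwell seconds* per cell (not fix counts), so irregular
sampling does not distort the map. Rendering to PNG is a thin layer over
matplotlib; the tested surface is the grid/timeline data itself.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .home import mean_subtract
from .traces import DEFAULT_SESSION_GAP, RecordingSession, Trace

DEFAULT_BINS = 100
_PAD_FRACTION = 0.05


def scatter_data(trace: Trace) -> pd.DataFrame:
    """Mean-subtracted (dlat, dlon) pairs for scatterplotting; one row
    per fix, centroid at the origin, no absolute coordinates."""
    return mean_subtract(trace)


@dataclass
class HeatGrid:
    """Dwell-time grid in the mean-subtracted frame."""

    lat_edges: np.ndarray  # len n_bins+1, degrees relative to centroid
    lon_edges: np.ndarray
    cell_seconds: np.ndarray  # shape (n_lat_bins, n_lon_bins)
    period: tuple[pd.Timestamp, pd.Timestamp] | None
    empty: bool = False  # no fixes fell inside the period

    @property
    def total_seconds(self) -> float:
        return float(self.cell_seconds.sum())

    def to_flat_json(self) -> dict:
        return {
            "lat_edges": self.lat_edges.tolist(),
            "lon_edges": self.lon_edges.tolist(),
            "cell_seconds": self.cell_seconds.tolist(),
            "period": [str(p) for p in self.period] if self.period else None,
            "empty": self.empty,
        }


def heat_grid(
    trace: Trace,
    period: tuple[pd.Timestamp, pd.Timestamp] | None = None,
    n_bins: int = DEFAULT_BINS,
    session_gap: pd.Timedelta = DEFAULT_SESSION_GAP,
    weight: str = "dwell",  # or "count"
) -> HeatGrid:
    """Bin in-period fixes into an ``n_bins x n_bins`` dwell-time grid.

    Each inter-fix interval inside a recording session credits its full
    duration to the cell of its *earlier* fix (the same left-constant
    convention the metrics use), so the grid mass equals the in-period
    recorded seconds exactly. ``weight="count"`` counts fixes instead.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    sub = mean_subtract(trace)
    ts = trace.points["timestamp"]
    n = len(trace)

    # interval seconds attributed to each fix (last fix of a session: 0)
    w = np.zeros(n)
    if n > 1:
        gap = ts.diff().dt.total_seconds().to_numpy()[1:]
        ok = gap <= session_gap.total_seconds()
        w[:-1] = np.where(ok, gap, 0.0)

    if period is not None:
        start, end = period
        in_period = (ts >= start) & (ts < end)
        in_period = in_period.to_numpy()
    else:
        in_period = np.ones(n, dtype=bool)

    dlat = sub["dlat"].to_numpy()[in_period]
    dlon = sub["dlon"].to_numpy()[in_period]
    weights = w[in_period] if weight == "dwell" else np.ones(in_period.sum())

    if len(dlat) == 0:
        edges = np.linspace(-1e-6, 1e-6, n_bins + 1)
        return HeatGrid(edges, edges.copy(), np.zeros((n_bins, n_bins)),
                        period, empty=True)

    def _edges(vals: np.ndarray) -> np.ndarray:
        lo, hi = float(vals.min()), float(vals.max())
        span = hi - lo
        pad = span * _PAD_FRACTION if span > 0 else 1e-6
        return np.linspace(lo - pad, hi + pad, n_bins + 1)

    lat_edges = _edges(dlat)
    lon_edges = _edges(dlon)
    grid, _, _ = np.histogram2d(dlat, dlon, bins=[lat_edges, lon_edges],
                                weights=weights)
    return HeatGrid(lat_edges, lon_edges, grid, period)


@dataclass(frozen=True)
class TimelineBar:
    """Recorded intervals of one local calendar day."""

    date: _dt.date
    intervals: tuple  # of (start, end) local timestamps within the day


def recording_timeline(
    sessions: list[RecordingSession], timezone: str = "UTC"
) -> list[TimelineBar]:
    """Per-day recording bars; sessions are split at local midnight."""
    by_day: dict[_dt.date, list] = {}
    for s in sessions:
        cur = s.start.tz_convert(timezone)
        end = s.end.tz_convert(timezone)
        while True:
            next_midnight = (cur + pd.Timedelta(days=1)).normalize()
            stop = min(next_midnight, end)
            by_day.setdefault(cur.date(), []).append((cur, stop))
            if stop >= end:
                break
            cur = stop
    return [
        TimelineBar(date=d, intervals=tuple(ivs))
        for d, ivs in sorted(by_day.items())
    ]


# ---------------------------------------------------------------- rendering

def render_scatter(trace: Trace, ax=None):
    """Scatterplot of the mean-subtracted coordinates."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    sub = scatter_data(trace)
    ax.scatter(sub["dlon"], sub["dlat"], s=2, alpha=0.3)
    ax.set_xlabel("Δ longitude (deg)")
    ax.set_ylabel("Δ latitude (deg)")
    ax.set_title(f"Lifespace scatter — {trace.participant_id}")
    return ax


def render_heatmap(grid: HeatGrid, ax=None, log_scale: bool = True):
    """Render a dwell-time heat grid (hours per cell)."""
    import matplotlib.pyplot as plt
    from matplotlib.colors import LogNorm

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    vals = grid.cell_seconds / 3600.0
    norm = LogNorm(vmin=max(vals[vals > 0].min(), 1e-4), vmax=vals.max()) \
        if log_scale and (vals > 0).any() else None
    m = ax.pcolormesh(grid.lon_edges, grid.lat_edges, vals, norm=norm,
                      cmap="inferno")
    ax.figure.colorbar(m, ax=ax, label="dwell (h)")
    ax.set_xlabel("Δ longitude (deg)")
    ax.set_ylabel("Δ latitude (deg)")
    return ax


def render_timeline(bars: list[TimelineBar], ax=None):
    """Horizontal bars of recorded periods, one row per day."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, max(2, 0.25 * len(bars))))
    for i, bar in enumerate(bars):
        for start, end in bar.intervals:
            t0 = start.hour + start.minute / 60 + start.second / 3600
            t1 = t0 + (end - start).total_seconds() / 3600
            ax.barh(i, t1 - t0, left=t0, height=0.6, color="tab:blue")
    ax.set_yticks(range(len(bars)))
    ax.set_yticklabels([str(b.date) for b in bars], fontsize=6)
    ax.set_xlim(0, 24)
    ax.set_xlabel("hour of day")
    ax.invert_yaxis()
    return ax
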