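"""Home-location inference and the privacy transform.

Home is established from the data alone: fixes are binned on a fixed
latitude/longitude grid and the modal cell — the cell where the most
fixes (hence, at a steady sampling rate, the most time) were recorded —
is taken as home. The grid pitch defaults to 1e-4 degrees (~11 m),
matching typical outdoor smartphone GPS accuracy of ~10 m, so the noise
cloud around a true dwell location concentrates in a handful of cells.

``mean_subtract`` is the privacy transform used for all reporting:
coordinates with the trace centroid removed preserve the shape of a
person's movements while revealing no absolute location.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geo import EarthModel, GeoPoint, haversine_km_arrays
from .traces import Trace

DEFAULT_CELL_SIZE_DEG = 1e-4


@dataclass(frozen=True)
class HomeRadiusPolicy:
    """Radius (km) within which a fix counts as at home; boundary is
    inclusive (a fix at exactly the radius is at home)."""

    radius_km: float = 0.5

    def __post_init__(self) -> None:
        if self.radius_km <= 0:
            raise ValueError(f"radius_km must be positive, got {self.radius_km}")


@dataclass(frozen=True)
class HomeEstimate:
    """The inferred home coordinate and how it was derived."""

    home: GeoPoint
    modal_cell: tuple[int, int]
    cell_size_deg: float
    support: int
    support_fraction: float

    def to_dict(self) -> dict:
        return {
            "latitude": self.home.latitude_deg,
            "longitude": self.home.longitude_deg,
            "modal_cell": list(self.modal_cell),
            "cell_size_deg": self.cell_size_deg,
            "support": self.support,
            "support_fraction": self.support_fraction,
        }


def infer_home(trace: Trace, cell_size_deg: float = DEFAULT_CELL_SIZE_DEG) -> HomeEstimate:
    """Infer home as the modal grid cell of the recorded fixes.

    Fixes are binned with ``floor(coord / cell_size_deg)``; the cell
    with the most fixes wins, ties broken by the lexicographically
    smallest ``(lat_index, lon_index)``. The returned coordinate is the
    arithmetic mean of the fixes inside the modal cell.
    """
    if len(trace) == 0:
        raise ValueError("cannot infer home from an empty trace")
    if cell_size_deg <= 0:
        raise ValueError(f"cell_size_deg must be positive, got {cell_size_deg}")

    lat = trace.points["latitude"].to_numpy()
    lon = trace.points["longitude"].to_numpy()
    ilat = np.floor(lat / cell_size_deg).astype(np.int64)
    ilon = np.floor(lon / cell_size_deg).astype(np.int64)

    cells = pd.DataFrame({"ilat": ilat, "ilon": ilon})
    counts = cells.value_counts(sort=False).reset_index(name="n")
    # modal cell; ties -> lexicographically smallest (ilat, ilon)
    counts = counts.sort_values(["n", "ilat", "ilon"], ascending=[False, True, True],
                                kind="stable")
    top = counts.iloc[0]
    mask = (ilat == top["ilat"]) & (ilon == top["ilon"])
    home = GeoPoint(float(lat[mask].mean()), float(lon[mask].mean()))
    support = int(top["n"])
    return HomeEstimate(
        home=home,
        modal_cell=(int(top["ilat"]), int(top["ilon"])),
        cell_size_deg=cell_size_deg,
        support=support,
        support_fraction=support / len(trace),
    )


def at_home_mask(
    trace: Trace,
    home: GeoPoint,
    policy: HomeRadiusPolicy = HomeRadiusPolicy(),
    earth: EarthModel = EarthModel(),
) -> np.ndarray:
    """Boolean per fix: within ``policy.radius_km`` of home (inclusive)."""
    d = haversine_km_arrays(
        trace.points["latitude"].to_numpy(),
        trace.points["longitude"].to_numpy(),
        home.latitude_deg,
        home.longitude_deg,
        earth,
    )
    return np.asarray(d) <= policy.radius_km


def mean_subtract(trace: Trace) -> pd.DataFrame:
    """Centroid-removed coordinates: ``(lat - mean lat, lon - mean lon)``.

    The output frame (columns ``dlat``, ``dlon``) has centroid (0, 0) to
    numerical tolerance and carries no absolute position.
    """
    df = trace.points
    if len(df) == 0:
        return pd.DataFrame(columns=["dlat", "dlon"])
    lat = df["latitude"].to_numpy()
    lon = df["longitude"].to_numpy()
    return pd.DataFrame({"dlat": lat - lat.mean(), "dlon": lon - lon.mean()})
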