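"""Great-circle geometry on the WGS84 sphere.

All public functions take and return decimal degrees; conversion to
radians happens internally. Distances are kilometers along a sphere of
radius :data:`EARTH_RADIUS_KM` (IUGG mean radius) unless an explicit
:class:`EarthModel` is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: IUGG mean Earth radius, kilometers.
EARTH_RADIUS_KM = 6371.0088


@dataclass(frozen=True)
class GeoPoint:
    """A WGS84 coordinate in decimal degrees."""

    latitude_deg: float
    longitude_deg: float

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude_deg <= 90.0:
            raise ValueError(
                f"latitude_deg must be in [-90, 90], got {self.latitude_deg}"
            )
        if not -180.0 <= self.longitude_deg <= 180.0:
            raise ValueError(
                f"longitude_deg must be in [-180, 180], got {self.longitude_deg}"
            )


@dataclass(frozen=True)
class EarthModel:
    """Spherical Earth of configurable radius (km)."""

    radius_km: float = EARTH_RADIUS_KM

    def __post_init__(self) -> None:
        if self.radius_km <= 0:
            raise ValueError(f"radius_km must be positive, got {self.radius_km}")


_DEFAULT_EARTH = EarthModel()


def haversine_km(a: GeoPoint, b: GeoPoint, earth: EarthModel = _DEFAULT_EARTH) -> float:
    """Great-circle distance between two points, in kilometers.

    Uses the haversine formula
    ``d = 2R asin(sqrt(sin^2(dphi/2) + cos(phi1) cos(phi2) sin^2(dlam/2)))``,
    which is numerically stable for small separations. Symmetric in its
    arguments; bounded by ``pi * R``.
    """
    return float(
        haversine_km_arrays(
            a.latitude_deg, a.longitude_deg, b.latitude_deg, b.longitude_deg, earth
        )
    )


def haversine_km_arrays(lat1, lon1, lat2, lon2, earth: EarthModel = _DEFAULT_EARTH):
    """Vectorized haversine over degree arrays (broadcasting allowed)."""
    phi1, lam1, phi2, lam2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    h = (
        np.sin((phi2 - phi1) / 2.0) ** 2
        + np.cos(phi1) * np.cos(phi2) * np.sin((lam2 - lam1) / 2.0) ** 2
    )
    # clip guards tiny negative/overshoot from rounding before the asin
    return 2.0 * earth.radius_km * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def distance_from_home_series(trace, home: GeoPoint, earth: EarthModel = _DEFAULT_EARTH):
    """Per-fix haversine distance to ``home``.

    Parameters
    ----------
    trace : Trace
        Chronologically sorted GPS trace.
    home : GeoPoint
        The inferred home coordinate.

    Returns
    -------
    pandas.Series
        Distance in km, indexed by the trace timestamps, one entry per
        fix in trace order. Empty trace gives an empty series.
    """
    import pandas as pd

    df = trace.points
    d = haversine_km_arrays(
        df["latitude"].to_numpy(), df["longitude"].to_numpy(),
        home.latitude_deg, home.longitude_deg, earth,
    )
    return pd.Series(d, index=df["timestamp"], name="distance_km")
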