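"""Study-level configuration aggregating each stage's tunables.

The defaults are the analysis constants the pipeline is built around: a
500 m home radius, a 15 min minimum trip duration, a 1e-4 degree
(~11 m) home-inference grid and a 5 min session gap. All of them are
one-flag changes for sensitivity runs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from .metrics import DAILY_DISTANCE_MODES


@dataclass(frozen=True)
class StudyConfig:
    timezone: str = "UTC"
    cell_size_deg: float = 1e-4
    radius_km: float = 0.5
    min_trip_duration_min: float = 15.0
    count_open_trips: bool = False
    session_gap_min: float = 5.0
    daily_distance_mode: str = "max_home_distance"
    heatmap_bins: int = 100

    def __post_init__(self) -> None:
        if self.cell_size_deg <= 0:
            raise ValueError("cell_size_deg must be positive")
        if self.radius_km <= 0:
            raise ValueError("radius_km must be positive")
        if self.min_trip_duration_min < 0:
            raise ValueError("min_trip_duration_min must be >= 0")
        if self.session_gap_min <= 0:
            raise ValueError("session_gap_min must be positive")
        if self.daily_distance_mode not in DAILY_DISTANCE_MODES:
            raise ValueError(
                f"daily_distance_mode must be one of {DAILY_DISTANCE_MODES}"
            )
        if self.heatmap_bins < 1:
            raise ValueError("heatmap_bins must be >= 1")

    @property
    def session_gap(self) -> pd.Timedelta:
        return pd.Timedelta(minutes=self.session_gap_min)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        """Stable short hash naming this configuration in outputs."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
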