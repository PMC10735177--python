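"""Containers and parameter blocks for the GPS pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd


@dataclass
class GpsTrack:
    """Time-ordered GPS fixes for one participant-day on one device.

    Attributes
    ----------
    t : seconds since epoch (float), strictly increasing
    lat, lon : decimal degrees
    speed_kmh : logged speed per fix, or None when the device logs none
    device : device identifier ("qstarz", "ticwatch_s2", ...)
    """

    t: np.ndarray
    lat: np.ndarray
    lon: np.ndarray
    speed_kmh: Optional[np.ndarray] = None
    device: str = ""

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        if self.speed_kmh is not None:
            self.speed_kmh = np.asarray(self.speed_kmh, dtype=float)
        self.validate()

    def validate(self):
        n = len(self.t)
        if len(self.lat) != n or len(self.lon) != n:
            raise ValueError("t, lat, lon must have equal length")
        if self.speed_kmh is not None and len(self.speed_kmh) != n:
            raise ValueError("speed_kmh length mismatch")
        if n and (np.abs(self.lat) > 90).any():
            raise ValueError("latitude out of range")
        if n and (np.abs(self.lon) > 180).any():
            raise ValueError("longitude out of range")
        if n > 1 and not (np.diff(self.t) > 0).all():
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self):
        return len(self.t)

    def slice(self, mask_or_idx) -> "GpsTrack":
        sp = None if self.speed_kmh is None else self.speed_kmh[mask_or_idx]
        return GpsTrack(self.t[mask_or_idx], self.lat[mask_or_idx],
                        self.lon[mask_or_idx], sp, self.device)

    def time_window(self, t0: float, t1: float) -> "GpsTrack":
        return self.slice((self.t >= t0) & (self.t <= t1))

    def to_frame(self) -> pd.DataFrame:
        d = {"t": self.t, "lat": self.lat, "lon": self.lon}
        if self.speed_kmh is not None:
            d["speed_kmh"] = self.speed_kmh
        df = pd.DataFrame(d)
        df["device"] = self.device
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, device: str = "") -> "GpsTrack":
        sp = df["speed_kmh"].to_numpy() if "speed_kmh" in df else None
        dev = device or (str(df["device"].iloc[0]) if "device" in df and len(df) else "")
        return cls(df["t"].to_numpy(), df["lat"].to_numpy(), df["lon"].to_numpy(), sp, dev)


@dataclass(frozen=True)
class TripDetectionParams:
    """Thresholds for cleaning, stop/trip segmentation and mode labeling.

    Defaults are the settings used for older-adult mobility work: a stop is
    ≥5 min within 75 m of the running median position, a >60 min gap breaks a
    stop, a move needs >3 min and ≥100 m span, trips with 90th-percentile
    speed ≥25 km/h are passive (motorized), and fixes faster than 160 km/h
    are implausible and dropped.
    """

    max_speed_kmh: float = 160.0
    stop_min_duration_s: float = 5 * 60.0
    stop_radius_m: float = 75.0
    stop_gap_break_s: float = 60 * 60.0
    move_min_duration_s: float = 3 * 60.0
    move_min_span_m: float = 100.0
    passive_speed_percentile: float = 90.0
    passive_speed_threshold_kmh: float = 25.0
    min_joint_wear_h: float = 8.0

    def __post_init__(self):
        for name in ("max_speed_kmh", "stop_min_duration_s", "stop_radius_m",
                     "stop_gap_break_s", "move_min_duration_s", "move_min_span_m",
                     "passive_speed_threshold_kmh", "min_joint_wear_h"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.passive_speed_percentile <= 100):
            raise ValueError("passive_speed_percentile must be in (0, 100]")

    def replace(self, **kw) -> "TripDetectionParams":
        return replace(self, **kw)


@dataclass
class Segment:
    """A stop or move interval of a segmented track.

    ``i0``/``i1`` index the first/last member point (inclusive) in the
    cleaned track the segmentation ran on.
    """

    kind: str  # "stop" | "move"
    i0: int
    i1: int
    start_t: float
    end_t: float
    centroid_lat: float  # median position for stops, mean for moves
    centroid_lon: float
    span_m: float  # greatest distance between two member points

    @property
    def duration_s(self) -> float:
        return self.end_t - self.start_t

    @property
    def n_points(self) -> int:
        return self.i1 - self.i0 + 1


@dataclass
class Trip:
    """A move segment promoted to a trip with duration, speed and mode."""

    segment: Segment
    duration_min: float
    p90_speed_kmh: float
    mode: str  # "active" | "passive"


@dataclass
class TripSummary:
    trips: list
    frequency: int
    total_duration_min: float
    active_duration_min: float
    passive_duration_min: float


@dataclass
class LifeSpaceSummary:
    """Daily life-space metrics in a local plane centered on home."""

    max_home_distance_m: float
    mch_area_m2: float
    mch_perimeter_m: float
    sde_center_xy: tuple
    sde_major_m: float
    sde_minor_m: float
    sde_theta_rad: float
    n_points: int
    degenerate_hull: bool = False
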