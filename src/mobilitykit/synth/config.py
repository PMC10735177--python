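"""Scenario configuration for the synthetic multi-device cohort.

Defaults emulate the validation study's setup: a 25-participant cohort
observed for 3 days, a 5 s GPS logger (Qstarz-style) worn alongside a
smartwatch logging at 20 s (S2-style) or 10 s / 5 s (Pro-3-style), a 30 Hz
reference accelerometer with a 25 Hz or 50 Hz watch accelerometer, walking
legs at 3–6 km/h and vehicle legs at 30–60 km/h, destination dwells of at
least 6 minutes (so every planted stop exceeds the 5-minute detection
threshold), 3 m positional noise (the logger's nominal accuracy), and
50–100-step self-counted walk tasks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import yaml

GPS_INTERVALS_S = {
    "qstarz": 5.0,
    "ticwatch_s2": 20.0,
    "ticwatch_pro3_periodic": 10.0,
    "ticwatch_pro3_stay": 5.0,
}
ACCEL_RATES_HZ = {
    "actigraph": 30.0,
    "ticwatch_s2": 25.0,
    "ticwatch_pro3": 50.0,
}


@dataclass(frozen=True)
class ScenarioConfig:
    n_participants: int = 25
    n_days: int = 3
    home_lat: float = 43.26
    home_lon: float = -79.92
    trips_per_day: tuple = (2, 6)  # move legs; realized as out-and-back pairs
    leg_duration_active_min: tuple = (8.0, 14.0)
    leg_duration_passive_min: tuple = (4.0, 10.0)
    leg_speed_active_kmh: tuple = (3.0, 6.0)
    leg_speed_passive_kmh: tuple = (30.0, 60.0)
    passive_trip_prob: float = 0.5
    stop_dwell_min: tuple = (6.0, 20.0)
    gps_noise_sd_m: float = 3.0
    gps_interval_s: dict = field(default_factory=lambda: dict(GPS_INTERVALS_S))
    dropout_prob: float = 0.02
    drift_max_m: float = 0.0  # optional slow random-walk drift (off by default)
    accel_rate_hz: dict = field(default_factory=lambda: dict(ACCEL_RATES_HZ))
    accel_noise_sd_g: float = 0.05
    fidget: bool = True  # small in-band movement during quiet sitting/standing
    walk_cadence_hz: tuple = (1.6, 2.2)
    walk_steps: tuple = (50, 100)
    wear_start_h: float = 8.0
    wear_end_h: float = 20.0
    nonwear_block_min: tuple = (95.0, 120.0)  # one off-wrist block per day
    seed: int = 0

    def __post_init__(self):
        if self.n_participants <= 0 or self.n_days <= 0:
            raise ValueError("cohort size and day count must be positive")
        for name in ("leg_speed_active_kmh", "leg_speed_passive_kmh",
                     "stop_dwell_min", "leg_duration_active_min",
                     "leg_duration_passive_min", "walk_cadence_hz"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must be a positive (low, high) range")
        for dev, iv in self.gps_interval_s.items():
            if iv <= 0:
                raise ValueError(f"gps_interval_s[{dev!r}] must be positive")
        for dev, r in self.accel_rate_hz.items():
            if r <= 0:
                raise ValueError(f"accel_rate_hz[{dev!r}] must be positive")
        if not (0 <= self.dropout_prob < 1):
            raise ValueError("dropout_prob must be in [0, 1)")
        if self.wear_end_h <= self.wear_start_h:
            raise ValueError("wear_end_h must exceed wear_start_h")
        # planted trips are observed between the two 75 m stop-radius
        # crossings; the shortest possible crossing-trimmed leg must still
        # exceed both move-detection thresholds (>3 min, >=100 m span)
        for dur_rng, spd_rng in ((self.leg_duration_active_min, self.leg_speed_active_kmh),
                                 (self.leg_duration_passive_min, self.leg_speed_passive_kmh)):
            v_min = spd_rng[0] / 3.6  # m/s
            min_leg_m = dur_rng[0] * 60.0 * v_min
            if min_leg_m - 150.0 < 100.0:
                raise ValueError("shortest planted leg spans under 100 m "
                                 "between stop-radius crossings; lengthen legs")
            if dur_rng[0] * 60.0 - 150.0 / v_min <= 3 * 60.0:
                raise ValueError("shortest planted trip lasts under 3 minutes "
                                 "between stop-radius crossings; lengthen legs "
                                 "or raise the minimum speed")
        if self.stop_dwell_min[0] * 60.0 <= 5 * 60.0:
            raise ValueError("stop_dwell_min must exceed the 5-minute stop "
                             "detection threshold")

    def replace(self, **kw) -> "ScenarioConfig":
        return replace(self, **kw)

    def gps_interval(self, device: str) -> float:
        try:
            return self.gps_interval_s[device]
        except KeyError:
            raise KeyError(f"unknown GPS device {device!r}; configured: "
                           f"{sorted(self.gps_interval_s)}") from None

    def accel_rate(self, device: str) -> float:
        try:
            return self.accel_rate_hz[device]
        except KeyError:
            raise KeyError(f"unknown accelerometer device {device!r}; "
                           f"configured: {sorted(self.accel_rate_hz)}") from None

    def to_yaml(self, path) -> None:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        for k, v in list(d.items()):
            if isinstance(v, list):
                d[k] = tuple(v)
        return cls(**d)
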