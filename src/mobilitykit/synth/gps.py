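"""Synthetic GPS tracks sampled from a day plan, with ground truth."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..geo import unproject_aeqd
from ..gps.types import GpsTrack
from .config import ScenarioConfig
from .plan import DayPlan, plan_day, _rng


@dataclass
class SnappedTrip:
    """A planted trip as observable on one device's sample grid."""

    start_t: float
    end_t: float
    mode: str
    speed_kmh: float
    distance_m: float

    @property
    def duration_s(self) -> float:
        return self.end_t - self.start_t


@dataclass
class GpsDayTruth:
    device: str
    interval_s: float
    plan: DayPlan
    trips: list  # SnappedTrip, time-ordered

    @property
    def n_trips(self) -> int:
        return len(self.trips)


def generate_gps_day(config: ScenarioConfig, participant: int, day: int,
                     device: str, plan: DayPlan | None = None):
    """Sample one device's track for one participant-day.

    Returns ``(GpsTrack, GpsDayTruth)``. The underlying movement plan is
    shared across devices (same seed); the device contributes its sampling
    interval, positional noise, optional slow drift, and dropouts.
    Raises ``KeyError`` for a device with no configured interval.
    """
    interval = config.gps_interval(device)
    if plan is None:
        plan = plan_day(config, participant, day)
    n = int(np.floor((plan.t_wear1 - plan.t_wear0) / interval)) + 1
    t = plan.t_wear0 + np.arange(n) * interval
    x, y = plan.position_at(t)

    truth_trips = [SnappedTrip(s, e, tr.mode, tr.speed_kmh, tr.distance_m)
                   for s, e, tr in plan.snapped_trips(t)]

    dev_idx = sorted(config.gps_interval_s).index(device)
    rng = _rng(config, participant, day, 1, dev_idx)
    if config.gps_noise_sd_m > 0:
        x = x + rng.normal(0.0, config.gps_noise_sd_m, n)
        y = y + rng.normal(0.0, config.gps_noise_sd_m, n)
    if config.drift_max_m > 0:
        # slow random-walk drift emulating poor-reception wander
        x = x + np.cumsum(rng.normal(0.0, config.drift_max_m / np.sqrt(n), n))
        y = y + np.cumsum(rng.normal(0.0, config.drift_max_m / np.sqrt(n), n))
    if config.dropout_prob > 0:
        keep = rng.random(n) >= config.dropout_prob
        keep[0] = keep[-1] = True  # preserve the covered range
        t, x, y = t[keep], x[keep], y[keep]

    lat, lon = unproject_aeqd(x, y, config.home_lat, config.home_lon)
    track = GpsTrack(t, lat, lon, None, device)
    return track, GpsDayTruth(device, interval, plan, truth_trips)
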