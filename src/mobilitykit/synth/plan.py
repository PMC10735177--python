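"""Daily movement plans with exact ground truth.

A plan is a piecewise-constant-velocity path in a local plane centered on
home: the participant dwells at home, makes out-and-back excursions to
points of interest at a constant leg speed (walking or vehicle), and dwells
at the destination in between. The plan is fully determined by
(config.seed, participant, day) and is shared by every GPS device, which
merely samples it at its own interval.

Ground-truth trip times are anchored to the 75 m stop radius used by the
stop/trip detector's definition of "stopped": a trip runs from the moment
the participant leaves the 75 m disc around the origin stop to the moment
it enters the disc around the destination. Truth recorded per device is
additionally snapped to that device's sample grid (first/last sample
strictly outside the discs), since a sampled observer cannot see boundary
crossings between fixes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import ScenarioConfig

STOP_RADIUS_M = 75.0
DAY_S = 86400.0


@dataclass
class PlannedTrip:
    """One planted move leg. Times are radius-crossing times (continuous)."""

    start_t: float
    end_t: float
    mode: str  # "active" | "passive"
    speed_kmh: float
    distance_m: float  # full leg length between stop anchors
    origin_xy: tuple
    dest_xy: tuple

    @property
    def duration_s(self) -> float:
        return self.end_t - self.start_t


@dataclass
class PlannedStop:
    start_t: float
    end_t: float
    x: float
    y: float
    label: str  # "home" | "poi"


@dataclass
class DayPlan:
    """Waypoint path plus planted stop/trip truth for one participant-day."""

    participant: int
    day: int
    day_start_t: float
    t_wear0: float
    t_wear1: float
    wp_t: np.ndarray  # waypoint times (s)
    wp_x: np.ndarray  # local-plane meters east of home
    wp_y: np.ndarray  # meters north
    trips: list = field(default_factory=list)
    stops: list = field(default_factory=list)

    def position_at(self, t):
        """Path position (x, y) at times ``t`` (piecewise linear)."""
        t = np.asarray(t, dtype=float)
        return (np.interp(t, self.wp_t, self.wp_x),
                np.interp(t, self.wp_t, self.wp_y))

    def snapped_trips(self, sample_times: np.ndarray):
        """Trip (start, end) pairs as seen on a sample grid: first/last
        sample strictly outside the two stop discs. Trips the grid cannot
        resolve (no sample falls inside) are returned as-is."""
        out = []
        for tr in self.trips:
            inside = sample_times[(sample_times > tr.start_t) & (sample_times < tr.end_t)]
            if inside.size == 0:
                out.append((tr.start_t, tr.end_t, tr))
                continue
            out.append((float(inside[0]), float(inside[-1]), tr))
        return out


def _rng(config: ScenarioConfig, participant: int, day: int, channel: int,
         extra: int = 0) -> np.random.Generator:
    return np.random.default_rng(
        [config.seed & 0x7FFFFFFF, participant, day, channel, extra])


def plan_day(config: ScenarioConfig, participant: int, day: int) -> DayPlan:
    """Build the deterministic movement plan for one participant-day."""
    rng = _rng(config, participant, day, 0)
    t0 = day * DAY_S
    tw0 = t0 + config.wear_start_h * 3600.0
    tw1 = t0 + config.wear_end_h * 3600.0
    budget = tw1 - tw0

    k = int(rng.integers(config.trips_per_day[0], config.trips_per_day[1] + 1))
    n_exc = max(1, k // 2)

    # draw excursions until they fit in the wear window with home dwells
    while n_exc > 0:
        exc = []
        rtt = 0.0
        for _ in range(n_exc):
            passive = rng.random() < config.passive_trip_prob
            if passive:
                dur = rng.uniform(*config.leg_duration_passive_min) * 60.0
                v = rng.uniform(*config.leg_speed_passive_kmh)
            else:
                dur = rng.uniform(*config.leg_duration_active_min) * 60.0
                v = rng.uniform(*config.leg_speed_active_kmh)
            dwell = rng.uniform(*config.stop_dwell_min) * 60.0
            bearing = rng.uniform(0, 2 * np.pi)
            exc.append((passive, v, dur, dwell, bearing))
            rtt += 2 * dur + dwell
        min_home = config.stop_dwell_min[0] * 60.0
        if rtt + (n_exc + 1) * min_home <= budget:
            break
        n_exc -= 1
    if n_exc == 0:
        raise ValueError("wear window too short for a single excursion")

    # distribute the remaining time over the n_exc + 1 home dwells
    min_home = config.stop_dwell_min[0] * 60.0
    slack = budget - rtt - (n_exc + 1) * min_home
    w = rng.dirichlet(np.ones(n_exc + 1))
    home_dwells = min_home + w * slack

    wp_t, wp_x, wp_y = [tw0], [0.0], [0.0]
    trips, stops = [], []
    t = tw0

    def _advance(dt, x, y):
        nonlocal t
        t += dt
        wp_t.append(t)
        wp_x.append(x)
        wp_y.append(y)

    home_enter = tw0  # time the participant (re)entered the home disc
    for i, (passive, v, dur, dwell, bearing) in enumerate(exc):
        v_ms = v / 3.6
        cross = STOP_RADIUS_M / v_ms  # time to traverse the stop radius
        dist = v_ms * dur
        px, py = dist * np.sin(bearing), dist * np.cos(bearing)
        mode = "passive" if passive else "active"
        # dwell at home, then the out leg
        _advance(home_dwells[i], 0.0, 0.0)
        dep = t
        stops.append(PlannedStop(home_enter, dep + cross, 0.0, 0.0, "home"))
        _advance(dur, px, py)
        arr = t
        trips.append(PlannedTrip(dep + cross, arr - cross, mode, v, dist,
                                 (0.0, 0.0), (px, py)))
        # destination dwell, then the back leg
        _advance(dwell, px, py)
        ret = t
        stops.append(PlannedStop(arr - cross, ret + cross, px, py, "poi"))
        _advance(dur, 0.0, 0.0)
        trips.append(PlannedTrip(ret + cross, t - cross, mode, v, dist,
                                 (px, py), (0.0, 0.0)))
        home_enter = t - cross
    # final home dwell to the end of the wear window
    _advance(home_dwells[n_exc], 0.0, 0.0)
    stops.append(PlannedStop(home_enter, tw1, 0.0, 0.0, "home"))

    return DayPlan(participant, day, t0, tw0, tw1,
                   np.array(wp_t), np.array(wp_x), np.array(wp_y),
                   trips, stops)
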