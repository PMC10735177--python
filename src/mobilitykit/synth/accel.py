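"""Synthetic raw accelerometry with posture, step and wear ground truth.

The signal model is deliberately simple and fully labeled: a gravity vector
whose orientation encodes posture (longitudinal thigh axis loaded when
standing, perpendicular when sitting or lying), a walking oscillation —
fundamental plus a weak second harmonic at the step cadence, one cycle per
step — riding on the gravity axis, optional brief in-band "fidget" bursts so
quietly seated epochs still register nonzero activity counts, white sensor
noise, and exactly constant output while the device is off the body.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..accel.types import AccelStream
from .config import ScenarioConfig
from .plan import _rng, DAY_S

WALK_AMP_G = 0.35
WALK_HARMONIC = 0.25
FIDGET_AMP_G = 0.12
FIDGET_HZ = 1.5
FIDGET_PERIOD_S = 60.0
FIDGET_BURST_S = 2.0

_POSTURE_OF_STATE = {"sit": "sitting_lying", "lie": "sitting_lying",
                     "stand": "standing", "walk": "standing",
                     "nonwear": "nonwear"}


@dataclass
class ScheduleEntry:
    start_t: float
    end_t: float
    state: str  # sit | stand | lie | walk | nonwear
    cadence_hz: float | None = None  # walk only
    n_steps: int | None = None

    @property
    def duration_s(self) -> float:
        return self.end_t - self.start_t


def validate_schedule(schedule: list) -> None:
    """Entries must be positive-length, sorted and non-overlapping, tiling
    their span without gaps."""
    if not schedule:
        raise ValueError("empty schedule")
    for e in schedule:
        if e.end_t <= e.start_t:
            raise ValueError("schedule entry with non-positive duration")
    for a, b in zip(schedule[:-1], schedule[1:]):
        if b.start_t < a.end_t - 1e-9:
            raise ValueError("overlapping schedule entries")
        if b.start_t > a.end_t + 1e-9:
            raise ValueError("schedule has a gap")


@dataclass
class AccelDayTruth:
    schedule: list
    wear_intervals: list  # (t0, t1) worn
    walk_tasks: list  # (t0, t1, n_steps, cadence_hz)

    def posture_labels(self, epoch_times: np.ndarray, epoch_s: float = 60.0):
        """Majority-overlap posture truth per epoch."""
        out = np.full(len(epoch_times), "nonwear", dtype=object)
        for k, t0 in enumerate(epoch_times):
            t1 = t0 + epoch_s
            best, best_ov = "nonwear", 0.0
            for e in self.schedule:
                ov = min(t1, e.end_t) - max(t0, e.start_t)
                if ov > best_ov:
                    best_ov = ov
                    best = _POSTURE_OF_STATE[e.state]
            out[k] = best
        return out


def build_schedule(config: ScenarioConfig, participant: int, day: int) -> list:
    """Deterministic wear-window schedule: one off-body block, one to three
    self-counted walk tasks (50–100 steps), the rest sit/stand/lie blocks."""
    rng = _rng(config, participant, day, 2)
    tw0 = day * DAY_S + config.wear_start_h * 3600.0
    tw1 = day * DAY_S + config.wear_end_h * 3600.0

    specials = []
    nw_dur = rng.uniform(*config.nonwear_block_min) * 60.0
    if tw1 - 3600.0 - nw_dur > tw0 + 3600.0:  # window too short: skip the block
        nw_start = rng.uniform(tw0 + 3600.0, tw1 - 3600.0 - nw_dur)
        specials.append(ScheduleEntry(nw_start, nw_start + nw_dur, "nonwear"))
    n_walks = int(rng.integers(1, 4))
    attempts = 0
    while sum(1 for s in specials if s.state == "walk") < n_walks and attempts < 200:
        attempts += 1
        steps = int(rng.integers(config.walk_steps[0], config.walk_steps[1] + 1))
        cad = rng.uniform(*config.walk_cadence_hz)
        dur = steps / cad
        if tw1 - 300.0 - dur <= tw0 + 300.0:
            break
        t0 = rng.uniform(tw0 + 300.0, tw1 - 300.0 - dur)
        cand = ScheduleEntry(t0, t0 + dur, "walk", cad, steps)
        if all(cand.end_t + 120.0 <= s.start_t or cand.start_t >= s.end_t + 120.0
               for s in specials):
            specials.append(cand)
    specials.sort(key=lambda e: e.start_t)

    entries = []
    t = tw0
    states = np.array(["sit", "stand", "lie"])
    weights = np.array([0.5, 0.3, 0.2])
    for sp in specials + [ScheduleEntry(tw1, tw1 + 1.0, "sit")]:
        bound = min(sp.start_t, tw1)
        while t < bound - 1e-9:
            dur = rng.uniform(10.0, 30.0) * 60.0
            end = min(t + dur, bound)
            if bound - end < 60.0:  # avoid slivers
                end = bound
            entries.append(ScheduleEntry(t, end, str(rng.choice(states, p=weights))))
            t = end
        if sp.end_t <= tw1:
            entries.append(sp)
            t = sp.end_t
    validate_schedule(entries)
    return entries


def generate_accel_stream(config: ScenarioConfig, participant: int, day: int,
                          device: str, placement: str,
                          schedule: list | None = None):
    """Synthesize one device's raw stream over the wear window.

    Returns ``(AccelStream, AccelDayTruth)``. ``placement`` fixes the
    gravity-axis convention: on the thigh the longitudinal axis (column 0)
    carries gravity while standing; on the wrist axis 2 carries gravity
    except when lying.
    """
    rate = config.accel_rate(device)
    if schedule is None:
        schedule = build_schedule(config, participant, day)
    else:
        validate_schedule(schedule)
    t0 = schedule[0].start_t
    t1 = schedule[-1].end_t
    n = int(round((t1 - t0) * rate))
    data = np.zeros((n, 3))
    dev_idx = sorted(config.accel_rate_hz).index(device)
    rng = _rng(config, participant, day, 3, dev_idx)

    gravity_axis = {
        ("thigh", "sit"): 2, ("thigh", "lie"): 2, ("thigh", "stand"): 0,
        ("thigh", "walk"): 0, ("thigh", "nonwear"): 2,
        ("wrist", "sit"): 2, ("wrist", "lie"): 0, ("wrist", "stand"): 2,
        ("wrist", "walk"): 2, ("wrist", "nonwear"): 2,
    }

    wear_intervals, walk_tasks = [], []
    for e in schedule:
        i0 = int(round((e.start_t - t0) * rate))
        i1 = int(round((e.end_t - t0) * rate))
        m = i1 - i0
        if m <= 0:
            continue
        tau = np.arange(m) / rate  # time since entry start
        ax = gravity_axis[(placement, e.state)]
        seg = np.zeros((m, 3))
        seg[:, ax] = 1.0
        if e.state == "walk":
            f = e.cadence_hz
            osc = WALK_AMP_G * (np.sin(2 * np.pi * f * tau)
                                + WALK_HARMONIC * np.sin(4 * np.pi * f * tau))
            seg[:, ax] += osc
        elif e.state in ("sit", "stand", "lie") and config.fidget:
            phase = rng.uniform(0.0, FIDGET_PERIOD_S)
            burst = ((tau + phase) % FIDGET_PERIOD_S) < FIDGET_BURST_S
            seg[burst, ax] += FIDGET_AMP_G * np.sin(2 * np.pi * FIDGET_HZ * tau[burst])
        if e.state != "nonwear":
            if config.accel_noise_sd_g > 0:
                seg += rng.normal(0.0, config.accel_noise_sd_g, (m, 3))
            if not wear_intervals or wear_intervals[-1][1] < e.start_t - 1e-9:
                wear_intervals.append([e.start_t, e.end_t])
            else:
                wear_intervals[-1][1] = e.end_t
            if e.state == "walk":
                walk_tasks.append((e.start_t, e.end_t, e.n_steps, e.cadence_hz))
        else:
            # off the body: rng stream stays aligned across wear layouts
            rng.normal(0.0, 1.0, 1)
        data[i0:i1] = seg

    stream = AccelStream(rate, data, placement, t0)
    truth = AccelDayTruth(schedule, [tuple(w) for w in wear_intervals], walk_tasks)
    return stream, truth
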