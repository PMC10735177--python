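"""Self-report diaries with configurable reporting error."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .accel import AccelDayTruth, _POSTURE_OF_STATE
from .config import ScenarioConfig
from .plan import _rng


def generate_diary(config: ScenarioConfig, participant: int, day: int,
                   truth: AccelDayTruth,
                   report_error_sd_min: float = 2.0) -> pd.DataFrame:
    """Diary rows derived from the true schedule: one row per activity bout
    (with its posture), per walk task (with the self-counted steps), and per
    wear-on/off interval. Start and end times are independently jittered by
    N(0, ``report_error_sd_min``) minutes; with error 0 the diary equals the
    truth. Self-counted steps are reported exactly (the protocol has the
    participant count them)."""
    rng = _rng(config, participant, day, 4)
    sd_s = report_error_sd_min * 60.0

    def jit(t):
        return float(t) + (rng.normal(0.0, sd_s) if sd_s > 0 else 0.0)

    rows = []
    for e in truth.schedule:
        if e.state == "nonwear":
            continue
        rows.append({"kind": "activity", "label": e.state,
                     "posture": _POSTURE_OF_STATE[e.state],
                     "start_t": jit(e.start_t), "end_t": jit(e.end_t),
                     "steps": e.n_steps if e.state == "walk" else np.nan})
    for (t0, t1, steps, _cad) in truth.walk_tasks:
        rows.append({"kind": "walk_task", "label": "walk",
                     "posture": "standing", "start_t": jit(t0),
                     "end_t": jit(t1), "steps": steps})
    for (t0, t1) in truth.wear_intervals:
        rows.append({"kind": "wear", "label": "worn", "posture": "",
                     "start_t": jit(t0), "end_t": jit(t1), "steps": np.nan})
    df = pd.DataFrame(rows)
    return df.sort_values(["kind", "start_t"], kind="stable").reset_index(drop=True)
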