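"""Write a small synthetic cohort to disk in the supported file formats.

Each participant-day gets: a Qstarz-dialect GPS CSV plus generic CSVs for
the watch configurations, raw tri-axial accelerometer CSVs for the wrist
devices, a diary CSV with jittered self-report times, and the scenario YAML
for exact reproduction.
"""

from pathlib import Path

from mobilitykit.gps.io import write_generic_csv, write_qstarz_csv
from mobilitykit.accel.io import write_accel_csv
from mobilitykit.synth import (ScenarioConfig, build_schedule,
                               generate_accel_stream, generate_diary,
                               generate_gps_day, plan_day)

out = Path("cohort_demo")
cfg = ScenarioConfig(n_participants=2, n_days=1, seed=42)
out.mkdir(exist_ok=True)
cfg.to_yaml(out / "scenario.yaml")

for pid in range(cfg.n_participants):
    pdir = out / f"p{pid:03d}"
    pdir.mkdir(exist_ok=True)
    for day in range(cfg.n_days):
        plan = plan_day(cfg, pid, day)
        for device in ("qstarz", "ticwatch_s2"):
            track, truth = generate_gps_day(cfg, pid, day, device, plan)
            path = pdir / f"d{day}_{device}.csv"
            (write_qstarz_csv if device == "qstarz" else write_generic_csv)(track, path)
            print(f"{path}: {len(track)} fixes, {truth.n_trips} planted trips")
        schedule = build_schedule(cfg, pid, day)
        for device in ("actigraph", "ticwatch_s2"):
            stream, truth_a = generate_accel_stream(cfg, pid, day, device,
                                                    "wrist", schedule)
            path = pdir / f"d{day}_{device}_wrist.csv"
            write_accel_csv(stream, path)
            print(f"{path}: {len(stream)} samples at {stream.rate_hz:.0f} Hz")
        diary = generate_diary(cfg, pid, day, truth_a, report_error_sd_min=2.0)
        diary.to_csv(pdir / f"d{day}_diary.csv", index=False)
        print(f"{pdir}/d{day}_diary.csv: {len(diary)} rows "
              f"({(diary.kind == 'walk_task').sum()} walk tasks)")
print(f"\ncohort written under {out}/ (times jittered by 2 min reporting error)")
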