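# mobilitykit

Multi-sensor mobility analysis for device-validation studies in older
adults: GPS life-space and trip metrics, raw-accelerometry activity, wear,
posture and step metrics, and the method-agreement statistics used to
compare a consumer smartwatch against reference devices — plus a synthetic
multi-device cohort generator with exact ground truth, so the whole chain
is testable without participant data.

It is written for researchers in mobility epidemiology and digital health
who need a reproducible, scriptable version of the classic validation
workflow: wear a reference GPS logger and accelerometer alongside a test
device, process both identically, and quantify agreement.

## What it computes

**GPS** (`mobilitykit.gps`) — tracks are cleaned (fixes >160 km/h dropped),
then segmented by a greedy stay-point detector: a *stop* is ≥5 min spent
within 75 m of the running median position (a >60 min gap splits stops); a
*move* between stops becomes a trip when it lasts >3 min and spans ≥100 m.
A trip is *passive* (motorized) iff its 90th-percentile speed p₉₀ ≥
25 km/h, else *active*. Daily life-space metrics: farthest distance from
home, minimum convex hull (area, perimeter) and the standard deviational
ellipse, all in a local plane centered on home. Device pairs are trimmed to
their common time range; days with <8 h joint coverage are excluded.

**Accelerometry** (`mobilitykit.accel`) — raw tri-axial g at 25/30/50 Hz is
resampled to 30 Hz and converted to per-axis activity counts per 60 s epoch
(band-pass 0.25–2.5 Hz, clip, dead band, quantize, sum). The vector
magnitude VM = √(x²+y²+z²) drives the sedentary cut: sedentary iff
VM < 2,860 counts/min. Non-wear is ≥90 min of zero counts allowing ≤2 min
interruptions flanked by ≥30 min zeros. Thigh streams yield posture
(sitting/lying vs standing from thigh inclination and movement); wrist
streams yield steps (adaptive peak detection in walk-task windows).

**Agreement** (`mobilitykit.agreement`) — Bland–Altman bias with 95% limits
of agreement (bias ± 1.96·SD of paired differences), percent agreement
(test/reference × 100, raw and symmetrized), Spearman's ρ, and paired
t / Wilcoxon tests with an automatic normality gate at α = 0.05.

**Synthesis and orchestration** (`mobilitykit.synth`, `mobilitykit.study`)
— seeded cohorts with planted trips (known times, modes, speeds), posture
schedules, walk tasks with exact step counts, off-body blocks and jittered
diaries; `run_study` runs every pipeline per participant-day and emits the
full agreement report.

## Worked example

`python examples/gps_day.py` segments one synthetic participant-day and
prints:

```
track: 8469 fixes at 5 s interval

segments: ['stop', 'move', 'stop', 'move', 'stop']
detected 2 trips (truth planted 2); total 15.0 min (15.0 active / 0.0 passive)
  detected   7.5 min active  (p90   9.5 km/h) | truth   7.5 min active
  detected   7.5 min active  (p90   9.2 km/h) | truth   7.5 min active

life-space: farthest 684 m from home, hull area 13861 m^2, perimeter 1414 m
```

The day contained one out-and-back walking excursion: the detector finds
both planted legs, their durations match the ground truth to within one 5 s
sampling interval, and both are labeled active (p₉₀ ≈ 9.5 km/h < 25 km/h).
Other capabilities each have a script under `examples/` (`accel_day.py`,
`agreement_demo.py`, `simulate_cohort.py`, `full_study.py`), and a thin CLI
mirrors them (`mobilitykit simulate|gps|accel|run`).

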