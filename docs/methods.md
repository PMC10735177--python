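# Methods

`mobilitykit` implements the analysis chain used to validate consumer
smartwatches against reference devices for older-adult mobility monitoring:
GPS life-space and trip metrics, raw-accelerometry activity/wear/posture
metrics, and the method-agreement statistics that compare devices. Because
studies of this kind rarely deposit participant data, the package ships a
synthetic cohort generator with exact ground truth; every pipeline stage is
validated against planted structure or an independent brute-force oracle.

## GPS pipeline

**Cleaning.** Fixes faster than 160 km/h are implausible for urban travel
and removed. A fix's speed is the logged speed when the device records one,
otherwise the haversine distance over the time gap to the previous
*retained* fix, so one bad fix cannot cascade. A single fix is always kept
(no speed is computable).

**Distances.** All point-to-point distances use the haversine formula on a
6,371 km sphere — datum-free and accurate to well under 0.5% at city scale.
Hull and ellipse computations project fixes onto a local
azimuthal-equidistant plane centered on the participant's home, where
distances from the center are exact and areas carry m² units.

**Stop/trip segmentation.** A greedy stay-point detector in the
Montoliu/Fillekes tradition: a candidate stop grows forward while every
member fix stays within 75 m of the running median position; a candidate
spanning ≥5 min commits as a stop; a >60 min transmission gap always splits
segments. Runs between stops become moves (trips) when they last >3 min and
span ≥100 m between their farthest points; shorter runs merge into a
flanking stop (ties resolve toward stops — these detectors are
stop-greedy). The incremental implementation certifies the
all-members-within-radius invariant with a conservative drift bound and
falls back to a full vectorized re-check when the bound cannot certify, so
its output is identical to the naive quadratic algorithm (and is tested
against one).

Committed stops are then *boundary-adjusted* against their final median:
edge members farther than 75 m are released to the neighbouring move, and
neighbouring fixes inside 75 m are absorbed, iterated to a fixed point.
The rationale: "stopped" is defined as being within 75 m of the stop
anchor, so a trip properly runs from the moment the participant crosses
that radius outward to the moment they cross it inward at the destination.
Without this step the growing median drags roughly one radius of each
walking leg into the flanking stops, biasing trip durations by one to three
minutes; with it, detected boundaries land on the radius crossings to
within one sampling interval on clean data. The synthetic ground truth
defines planted trip times the same way (see below), so detector and truth
measure the same quantity.

**Mode.** A trip is passive (motorized) iff the 90th percentile of its
member-fix speeds is ≥25 km/h, else active. The boundary is sharp and
tested at the cut.

**Life-space.** Farthest distance from home is the maximum planar distance
in the home-centered projection. The minimum convex hull (shapely) reports
shoelace area and perimeter; point sets that are collinear to rounding are
flagged degenerate and report zero area with the extreme-point separation
as the perimeter (the continuous limit of the shoelace formula). The
standard deviational ellipse uses the n-denominator covariance (the common
GIS convention) with 1-SD axes; orientation is the major-axis angle.

**Alignment.** Device pairs are trimmed to the intersection of their
covered time ranges; a day with under 8 h of joint coverage is flagged
invalid and excluded (with a logged reason), not an error.

**Day convention.** A "day" is a local calendar date; trips crossing
midnight belong to their start date. Timestamps are timezone-naive local
seconds.

## Accelerometry pipeline

**Counts.** Activity counts follow the openly documented actigraphy chain:
band-pass 0.25–2.5 Hz (3rd-order Butterworth, causal, initial state matched
to the first sample so pure gravity produces no startup transient), clip at
the 2.13 g saturation, decimate to 10 Hz, rectify, zero the sub-sensitivity
dead band (0.068 g), quantize at 1/128 g, and sum per second then per 60 s
epoch. Counts are integers, non-negative, and invariant to any DC offset.
Streams must be at the 30 Hz reference rate; watch streams are linearly
interpolated to it first (`resample`), preserving duration to within one
sample period.

**Vector magnitude and intensity.** VM is the per-epoch Euclidean norm of
the three axis counts. An epoch is sedentary iff VM < 2,860 counts/min —
the wrist cut-point with light and moderate/vigorous collapsed into
"non-sedentary" (VM = 2,860 is non-sedentary; the cut is exact and tested).
Intensity is only defined on wear epochs, and sedentary + non-sedentary
minutes always equal total wear minutes.

**Non-wear (90/2/30 rule).** Non-wear is ≥90 consecutive minutes of zero
counts, tolerating nonzero interruptions of ≤2 min each when flanked by
≥30 min of zeros on both sides. We interpret the allowance per interruption
(several allowed interruptions may occur inside one long non-wear block)
and apply the rule to VM counts; both choices are configurable because the
underlying rule text does not fix them. Interruptions at the series
boundary have no flank and never qualify. The run-based O(n) implementation
is tested epoch-for-epoch against an exhaustive window-scanning reference
on 1,000 random run-structured days.

**Posture.** For thigh-worn streams only (wrist placement is refused): a
0.5 Hz low-pass isolates gravity; thigh inclination is the angle between
the longitudinal (hip-to-knee) axis and vertical. Low-movement epochs are
standing when mean inclination <45°, sitting/lying otherwise; epochs with
VM counts ≥2,000 are stepping and inherit the standing class. The 45° and
2,000-count defaults are package choices (the commercial algorithm's
constants are unpublished): 45° bisects the vertical/horizontal thigh
orientations, and 2,000 counts sits an order of magnitude above stationary
fidgeting (~100–600 counts) and far below walking (~10,000+). The first and
last 45 s of any labeled task window are excluded from evaluation to cover
transitions and self-report clock error.

**Steps.** Steps are peaks of the 0.5–5 Hz band-passed vector magnitude
above an adaptive threshold — 30% of the 95th-percentile amplitude, floored
at 0.05 g — separated by ≥0.3 s. The relative threshold makes counts
invariant to amplitude scaling; the floor keeps a static signal at zero
steps. Steps are evaluated inside diary-declared walk-task windows,
mirroring the validation protocol.

## Agreement statistics

Bland–Altman bias is the mean reference−test difference with 95% limits of
agreement at bias ± 1.96·sample SD (n−1). Percent agreement is the per-pair
(test/reference)×100 averaged over pairs, reported two ways: the raw mean
ratio (which exceeds 100 under over-reporting) and a symmetrized version,
100 − |ratio − 100| per pair floored at 0, which penalizes deviation in
either direction; both are emitted because the raw form alone cannot
distinguish compensating errors. Zero-reference pairs are excluded with a
warning. Paired differences are tested with a paired t-test when a
Shapiro–Wilk check on the differences does not reject normality at α=0.05,
and the Wilcoxon signed-rank test otherwise (the gate is automated; it can
be forced either way). Spearman's rho uses average ranks and is flagged
undefined for constant series. All statistics are invariant to pair order.

## Synthetic cohort

The generator emulates the validation study's field setup with exact,
seeded ground truth. Defaults: 25 participants × 3 days; wear window
08:00–20:00; GPS at 5 s (reference logger), 20 s (watch), 10 s / 5 s
(newer-watch configurations); accelerometers at 30 Hz (reference), 25 or
50 Hz (watch).

**Movement.** Each day is a piecewise-constant-velocity path: home dwells
alternate with out-and-back excursions to points of interest; walking legs
run 3–6 km/h for 8–14 min, vehicle legs 30–60 km/h for 4–10 min, and
destination dwells last 6–20 min (always above the 5-min stop threshold).
The config validates that even the slowest leg of each mode exceeds both
move-detection thresholds *after* subtracting the time spent inside the two
75 m stop discs (>3 min and ≥100 m between crossings) — a slow leg loses up
to three minutes to the discs, and without this check a planted trip could
sit exactly on the detection boundary. A correct detector must therefore
recover all planted structure on clean data. Trip counts per day are drawn from 2–6 (realized in
out-and-back pairs). GPS noise is isotropic Gaussian in the local plane
(default 3 m, the reference logger's nominal accuracy); dropout is i.i.d.
Bernoulli (2%); an optional slow random-walk drift emulates poor reception
and is off by default. Ground-truth trip times are the 75 m radius-crossing
times, additionally snapped per device to the first/last sample outside
the discs — a sampled observer cannot see crossings between fixes, and this
makes "duration within one sampling interval" a well-posed target.

**Accelerometry.** Gravity orientation encodes posture (longitudinal thigh
axis loaded when standing, perpendicular when sitting/lying); walking adds
a fundamental-plus-second-harmonic oscillation at the step cadence
(1.6–2.2 Hz), one cycle per planted step, amplitude 0.35 g; quiet
sitting/standing adds brief 2 s in-band "fidget" bursts (0.12 g at 1.5 Hz,
once per minute) so worn-but-still epochs register nonzero counts, as real
wrists do; sensor noise is white with sd 0.05 g; off-body intervals are
exactly constant. With noise and fidget disabled, static postures have
per-sample vector magnitude exactly 1 g. Each day contains one 95–120 min
off-body block and 1–3 self-counted walk tasks of 50–100 steps.

**Diaries** replay the true schedule with start/end times independently
jittered by N(0, sd) minutes (configurable; 0 reproduces truth exactly);
self-counted steps are reported exactly, as the protocol has the
participant count them.

**What the generator does not model** — and hence what passing tests do not
establish about field data: multipath/urban-canyon GPS error and systematic
drift (only white noise and optional random walk), gait variability and
non-walking wrist dynamics beyond the fidget model, soft-tissue artifacts,
device clock drift, and diary errors beyond Gaussian time jitter. Recovery
rates here are upper bounds for real deployments.

## Numerical and design choices

- Stop detection recomputes the running median per added fix; the
  certificate/re-check scheme makes the fast path bit-equivalent to the
  naive one.
- Boundary adjustment iterates trim/absorb/merge to a fixed point with a
  hard cap of 25 iterations (reached only in adversarial geometry; the cap
  guarantees termination and determinism).
- Move span uses the convex hull of member fixes to reduce the farthest-
  pair scan; duplicates are collapsed first so dwell-heavy segments stay
  cheap.
- Partial trailing epochs are flagged and excluded from wear/intensity
  summaries (60 s epochs are the unit of analysis).
- The end-to-end study seeds every stream from
  (seed, participant, day, channel, device), so reruns are byte-identical
  and adding a device never perturbs another device's data.
- Problem sizes in the shipped checks — 100 synthetic participant-days per
  GPS condition, 1,000 days for the non-wear oracle, 1,000 replicates for
  test calibration, a 25×3 cohort for the end-to-end run — were chosen as
  the smallest sizes at which the binomial/Monte-Carlo margins of the
  claimed rates are comfortably resolved.

## Known limitations

- The percent-agreement pairing unit (participant-day vs participant) is a
  configuration choice; the two aggregations differ when day counts differ.
- The thigh-posture constants are defensible defaults, not a reproduction
  of the commercial algorithm.
- The counts chain follows the published description of the standard
  actigraphy algorithm; exact filter coefficients of the commercial
  implementation are not reproduced, and absolute count magnitudes may
  differ from device firmware by a scale factor. All classifications that
  depend on counts are validated on synthetic truth, not on count values
  from real hardware.
- Trips are assigned to their start date; cross-midnight travel is not
  split.
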