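"""Raw accelerometry to counts, wear, intensity, posture and steps.

Synthesizes a watch-style 25 Hz wrist stream and a 30 Hz thigh stream for
one day, resamples to the 30 Hz reference rate, computes 60 s activity
counts and their vector magnitude (VM), flags non-wear with the 90/2/30
zero-count rule, classifies epochs as sedentary (VM < 2,860) or
non-sedentary, classifies posture from the thigh inclination, and counts
steps inside the self-report walk-task windows.
"""

import numpy as np

from mobilitykit import accel as acc
from mobilitykit.synth import ScenarioConfig, build_schedule, generate_accel_stream

cfg = ScenarioConfig(seed=42)
schedule = build_schedule(cfg, participant=0, day=0)

wrist, truth = generate_accel_stream(cfg, 0, 0, "ticwatch_s2", "wrist", schedule)
print(f"wrist stream: {len(wrist)} samples at {wrist.rate_hz:.0f} Hz")

work = acc.resample(wrist, acc.COUNTS_RATE_HZ)
epochs = acc.compute_counts(work)
epochs.wear = acc.detect_nonwear(epochs.vm)
epochs.intensity = acc.classify_intensity(epochs.vm, wear=epochs.wear)
mins = acc.intensity_minutes(epochs.intensity)
validity = acc.day_validity(epochs.wear)

print(f"epochs: {epochs.n_epochs}; wear {validity.wear_min:.0f} min "
      f"(valid day: {validity.valid})")
print(f"sedentary {mins.sedentary_min:.0f} min, "
      f"non-sedentary {mins.non_sedentary_min:.0f} min")
true_nonwear = sum(e.duration_s for e in truth.schedule if e.state == "nonwear") / 60
print(f"true off-body time was {true_nonwear:.0f} min; "
      f"detected {epochs.n_epochs - validity.wear_min:.0f} min non-wear")

for t0, t1, true_steps, cad in truth.walk_tasks:
    got = acc.count_steps(wrist, t0, t1)
    print(f"walk task ({t1-t0:.0f} s at {cad:.1f} Hz): counted {got} steps, "
          f"participant counted {true_steps}")

thigh, _ = generate_accel_stream(cfg, 0, 0, "actigraph", "thigh", schedule)
posture = acc.classify_posture(thigh)
vals, counts = np.unique(posture, return_counts=True)
print("thigh posture epochs:", dict(zip(vals.tolist(), counts.tolist())))
print("(sitting/lying = thigh near horizontal; standing = thigh near vertical)")
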