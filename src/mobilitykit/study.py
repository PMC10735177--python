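"""End-to-end study runner.

Generates (or accepts) a multi-device cohort, runs the GPS and
accelerometry pipelines per participant-day, aligns device pairs, and emits
a validation report comparing a test device against a reference on every
mobility metric: trip frequency and duration, active/passive minutes,
life-space measures, sedentary/non-sedentary minutes, steps, and posture
accuracy against ground truth. Every exclusion (short joint coverage,
invalid wear day) is logged with its reason.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import accel as acc
from . import gps as gpsmod
from .agreement import PairedMeasurements, agreement_summary
from .synth import (ScenarioConfig, build_schedule, generate_accel_stream,
                    generate_gps_day, plan_day)

GPS_METRICS = ["trip_frequency", "trip_duration_min", "active_min",
               "passive_min", "max_home_distance_m", "mch_area_m2",
               "mch_perimeter_m"]
ACCEL_METRICS = ["sedentary_min", "non_sedentary_min", "steps"]


@dataclass
class StudyConfig:
    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    gps_reference: str = "qstarz"
    gps_test: str = "ticwatch_s2"
    accel_reference: str = "actigraph"
    accel_test: str = "ticwatch_s2"
    trip_params: gpsmod.TripDetectionParams = field(default_factory=gpsmod.TripDetectionParams)
    intensity_params: acc.IntensityParams = field(default_factory=acc.IntensityParams)
    wear_params: acc.WearParams = field(default_factory=acc.WearParams)
    posture_params: acc.PostureParams = field(default_factory=acc.PostureParams)
    pairing_unit: str = "participant_day"  # or "participant" (sum over days)


@dataclass
class ValidationReport:
    per_day: pd.DataFrame  # one row per participant-day-device
    steps_per_task: pd.DataFrame
    agreement: dict  # metric -> AgreementResult
    posture_accuracy_pct: dict  # class -> percent correct (reference thigh device)
    exclusions: list

    def agreement_frame(self) -> pd.DataFrame:
        rows = []
        for metric, res in self.agreement.items():
            rows.append({
                "metric": metric, "n": res.n,
                "mean_reference": res.mean_a, "mean_test": res.mean_b,
                "bias": res.bland_altman.bias,
                "loa_low": res.bland_altman.loa_low,
                "loa_high": res.bland_altman.loa_high,
                "pct_agreement_raw": res.pct.raw_mean_pct,
                "pct_agreement_symmetric": res.pct.symmetric_pct,
                "test": res.test.method, "statistic": res.test.statistic,
                "p_value": res.test.p_value,
                "spearman_rho": res.spearman.rho if res.spearman else np.nan,
            })
        return pd.DataFrame(rows)

    def to_markdown(self) -> str:
        lines = ["# Device validation report", "",
                 f"Participant-days analysed: "
                 f"{self.per_day[['participant', 'day']].drop_duplicates().shape[0]}",
                 f"Exclusions: {len(self.exclusions)}", "",
                 "## Agreement by metric", ""]
        af = self.agreement_frame()
        if len(af):
            lines.append(af.round(3).to_markdown(index=False))
        lines += ["", "## Posture accuracy vs ground truth (reference thigh device)", ""]
        for cls, pct in self.posture_accuracy_pct.items():
            lines.append(f"- {cls}: {pct:.1f}%")
        if self.exclusions:
            lines += ["", "## Exclusions", ""]
            lines += [f"- {e}" for e in self.exclusions]
        return "\n".join(lines) + "\n"

    def write(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.per_day.to_csv(out / "metrics_per_day.csv", index=False)
        self.steps_per_task.to_csv(out / "steps_per_task.csv", index=False)
        self.agreement_frame().to_csv(out / "agreement.csv", index=False)
        (out / "report.md").write_text(self.to_markdown())
        (out / "exclusions.log").write_text("\n".join(self.exclusions) + "\n")


def gps_day_metrics(track: gpsmod.GpsTrack, home_lat: float, home_lon: float,
                    params: gpsmod.TripDetectionParams) -> dict:
    """Run the full GPS pipeline on one track and return the daily metrics."""
    cleaned = gpsmod.clean_track(track, params)
    segments = gpsmod.detect_segments(cleaned, params)
    trips = gpsmod.summarize_trips(cleaned, segments, params)
    ls = gpsmod.lifespace_metrics(cleaned, home_lat, home_lon)
    return {"trip_frequency": trips.frequency,
            "trip_duration_min": trips.total_duration_min,
            "active_min": trips.active_duration_min,
            "passive_min": trips.passive_duration_min,
            "max_home_distance_m": ls.max_home_distance_m,
            "mch_area_m2": ls.mch_area_m2,
            "mch_perimeter_m": ls.mch_perimeter_m}


def posture_accuracy(pred: np.ndarray, truth: np.ndarray) -> dict:
    """Percent of correctly labeled epochs per truth class (and overall).

    Classes with no labeled epochs are omitted; an empty input raises."""
    pred = np.asarray(pred, dtype=object)
    truth = np.asarray(truth, dtype=object)
    if pred.size == 0 or pred.shape != truth.shape:
        raise ValueError("need equal-length, non-empty label series")
    out = {}
    for cls in ("sitting_lying", "standing"):
        mask = truth == cls
        if mask.any():
            out[cls] = float(np.mean(pred[mask] == cls)) * 100.0
    labeled = (truth == "sitting_lying") | (truth == "standing")
    if labeled.any():
        out["overall"] = float(np.mean(pred[labeled] == truth[labeled])) * 100.0
    return out


def _evaluation_epochs(schedule, epoch_times, epoch_s, trim_s):
    """Epoch indices fully inside a trimmed sit/stand/lie/walk task window."""
    idx = []
    for e in schedule:
        if e.state == "nonwear" or e.duration_s <= 2 * trim_s + epoch_s:
            continue
        t0, t1 = acc.trim_task_window(e.start_t, e.end_t, trim_s)
        sel = np.nonzero((epoch_times >= t0) & (epoch_times + epoch_s <= t1))[0]
        idx.extend(sel.tolist())
    return np.array(sorted(set(idx)), dtype=int)


def run_study(config: StudyConfig) -> ValidationReport:
    """Run the synthetic study end to end; deterministic given the config."""
    sc = config.scenario
    tp = config.trip_params
    rows, step_rows, exclusions = [], [], []
    posture_pred_all, posture_truth_all = [], []

    for pid in range(sc.n_participants):
        for day in range(sc.n_days):
            plan = plan_day(sc, pid, day)
            tag = f"participant {pid} day {day}"

            # ---- GPS arm
            track_ref, truth_ref = generate_gps_day(sc, pid, day, config.gps_reference, plan)
            track_test, _ = generate_gps_day(sc, pid, day, config.gps_test, plan)
            pair = gpsmod.align_devices(track_ref, track_test, tp)
            if not pair.valid:
                exclusions.append(f"{tag}: GPS joint coverage "
                                  f"{pair.overlap_h:.1f} h below threshold; day skipped")
            else:
                for role, trk in (("reference", pair.a), ("test", pair.b)):
                    m = gps_day_metrics(trk, sc.home_lat, sc.home_lon, tp)
                    rows.append({"participant": pid, "day": day, "arm": "gps",
                                 "role": role, "device": trk.device, **m})

            # ---- accelerometer arm (wrist: intensity, wear, steps)
            schedule = build_schedule(sc, pid, day)
            stream_ref, truth_a = generate_accel_stream(
                sc, pid, day, config.accel_reference, "wrist", schedule)
            stream_test, _ = generate_accel_stream(
                sc, pid, day, config.accel_test, "wrist", schedule)
            ep = {}
            wear = {}
            for role, stream in (("reference", stream_ref), ("test", stream_test)):
                work = stream if stream.rate_hz == acc.COUNTS_RATE_HZ \
                    else acc.resample(stream, acc.COUNTS_RATE_HZ)
                epochs = acc.compute_counts(work)
                epochs.wear = acc.detect_nonwear(epochs.vm, config.wear_params)
                ep[role] = epochs
                wear[role] = epochs.wear
            n_ep = min(e.n_epochs for e in ep.values())
            joint_wear = wear["reference"][:n_ep] & wear["test"][:n_ep]
            validity = acc.day_validity(joint_wear, config.wear_params)
            if not validity.valid:
                exclusions.append(f"{tag}: joint accelerometer wear "
                                  f"{validity.wear_min:.0f} min below threshold; day skipped")
            else:
                for role in ("reference", "test"):
                    epochs = ep[role]
                    labels = acc.classify_intensity(epochs.vm[:n_ep],
                                                    config.intensity_params,
                                                    joint_wear)
                    mins = acc.intensity_minutes(labels)
                    rows.append({"participant": pid, "day": day, "arm": "accel",
                                 "role": role,
                                 "device": (config.accel_reference if role == "reference"
                                            else config.accel_test),
                                 "sedentary_min": mins.sedentary_min,
                                 "non_sedentary_min": mins.non_sedentary_min})
                for ti, (t0, t1, true_steps, _cad) in enumerate(truth_a.walk_tasks):
                    step_rows.append({
                        "participant": pid, "day": day, "task": ti,
                        "true_steps": true_steps,
                        "reference": acc.count_steps(stream_ref, t0, t1),
                        "test": acc.count_steps(stream_test, t0, t1)})

            # ---- posture arm (thigh, reference device)
            thigh, truth_t = generate_accel_stream(
                sc, pid, day, config.accel_reference, "thigh", schedule)
            pred = acc.classify_posture(thigh, config.posture_params)
            ep_times = thigh.start_t + np.arange(len(pred)) * acc.EPOCH_S
            keep = _evaluation_epochs(schedule, ep_times, acc.EPOCH_S,
                                      config.posture_params.task_trim_s)
            if keep.size:
                truth_lab = truth_t.posture_labels(ep_times[keep])
                posture_pred_all.append(pred[keep])
                posture_truth_all.append(truth_lab)

    per_day = pd.DataFrame(rows)
    steps_df = pd.DataFrame(step_rows)

    agreement = {}
    if len(per_day):
        unit = ["participant"] if config.pairing_unit == "participant" else ["participant", "day"]
        for arm, metrics in (("gps", GPS_METRICS), ("accel", ACCEL_METRICS[:2])):
            sub = per_day[per_day["arm"] == arm]
            if not len(sub):
                continue
            piv = {role: sub[sub["role"] == role].groupby(unit).sum(numeric_only=True)
                   for role in ("reference", "test")}
            common = piv["reference"].index.intersection(piv["test"].index)
            for metric in metrics:
                if metric not in piv["reference"]:
                    continue
                a = piv["reference"].loc[common, metric].to_numpy(dtype=float)
                b = piv["test"].loc[common, metric].to_numpy(dtype=float)
                if len(a) >= 3 and (np.ptp(a - b) > 0 or np.ptp(a) > 0):
                    agreement[metric] = agreement_summary(
                        PairedMeasurements(a, b, metric))
    if len(steps_df) >= 3:
        agreement["steps"] = agreement_summary(PairedMeasurements(
            steps_df["reference"].to_numpy(dtype=float),
            steps_df["test"].to_numpy(dtype=float), "steps"))

    if posture_pred_all:
        acc_pct = posture_accuracy(np.concatenate(posture_pred_all),
                                   np.concatenate(posture_truth_all))
    else:
        acc_pct = {}
    return ValidationReport(per_day, steps_df, agreement, acc_pct, exclusions)
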