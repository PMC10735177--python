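import numpy as np
import pytest

from mobilitykit.accel import compute_counts, detect_nonwear, resample, COUNTS_RATE_HZ
from mobilitykit.geo import haversine_m
from mobilitykit.gps import derived_speeds_kmh
from mobilitykit.synth import (ScenarioConfig, ScheduleEntry, build_schedule,
                               generate_accel_stream, generate_diary,
                               generate_gps_day, plan_day, validate_schedule)


def test_same_seed_identical_tracks():
    cfg = ScenarioConfig(seed=5)
    t1, _ = generate_gps_day(cfg, 0, 0, "qstarz")
    t2, _ = generate_gps_day(cfg, 0, 0, "qstarz")
    np.testing.assert_array_equal(t1.t, t2.t)
    np.testing.assert_array_equal(t1.lat, t2.lat)
    np.testing.assert_array_equal(t1.lon, t2.lon)


def test_different_seeds_differ():
    t1, _ = generate_gps_day(ScenarioConfig(seed=5), 0, 0, "qstarz")
    t2, _ = generate_gps_day(ScenarioConfig(seed=6), 0, 0, "qstarz")
    assert not np.array_equal(t1.lat, t2.lat)


def test_unknown_device_rejected():
    with pytest.raises(KeyError, match="unknown GPS device"):
        generate_gps_day(ScenarioConfig(), 0, 0, "garmin")


def test_noise_free_speeds_bounded_by_passive_maximum(noise_free_config):
    trk, truth = generate_gps_day(noise_free_config, 1, 0, "qstarz")
    v = derived_speeds_kmh(trk)
    assert v.max() <= noise_free_config.leg_speed_passive_kmh[1] + 1e-6


def test_dwell_points_cluster_at_poi(noise_free_config):
    """A planted destination dwell of >=6 min at 5 s sampling leaves >=72
    consecutive fixes within 75 m of the POI."""
    plan = plan_day(noise_free_config, 2, 0)
    trk, _ = generate_gps_day(noise_free_config, 2, 0, "qstarz", plan)
    poi = next(s for s in plan.stops if s.label == "poi")
    mask = (trk.t >= poi.start_t) & (trk.t <= poi.end_t)
    from mobilitykit.geo import unproject_aeqd
    plat, plon = unproject_aeqd(poi.x, poi.y, noise_free_config.home_lat,
                                noise_free_config.home_lon)
    d = haversine_m(trk.lat[mask], trk.lon[mask], float(plat), float(plon))
    assert mask.sum() >= (poi.end_t - poi.start_t) / 5.0 - 1
    assert np.all(d <= 75.0 + 1e-6)


def test_planted_structure_respects_detection_thresholds():
    cfg = ScenarioConfig(seed=8)
    for pid in range(4):
        plan = plan_day(cfg, pid, 0)
        for tr in plan.trips:
            assert tr.duration_s > 3 * 60.0
            assert tr.distance_m - 150.0 >= 100.0
        for st in plan.stops:
            assert st.end_t - st.start_t > 5 * 60.0
        # stop/trip truth tiles the wear window without overlap
        ivals = sorted([(s.start_t, s.end_t) for s in plan.stops]
                       + [(t.start_t, t.end_t) for t in plan.trips])
        for (a0, a1), (b0, b1) in zip(ivals[:-1], ivals[1:]):
            assert abs(a1 - b0) < 1e-6


def test_trips_per_day_within_configured_range():
    cfg = ScenarioConfig(seed=9)
    lo, hi = cfg.trips_per_day
    for pid in range(5):
        n = len(plan_day(cfg, pid, 0).trips)
        assert lo <= n <= hi and n % 2 == 0


# ----------------------------------------------------------------- accel gen
def test_gravity_norm_is_one_during_static_postures():
    cfg = ScenarioConfig(seed=4, accel_noise_sd_g=0.0, fidget=False)
    tw0 = cfg.wear_start_h * 3600.0
    schedule = [ScheduleEntry(tw0, tw0 + 600.0, "stand"),
                ScheduleEntry(tw0 + 600.0, tw0 + 1200.0, "sit")]
    stream, _ = generate_accel_stream(cfg, 0, 0, "actigraph", "thigh", schedule)
    np.testing.assert_allclose(stream.vector_magnitude(), 1.0, atol=1e-12)
    # gravity decomposition: standing loads the longitudinal axis
    n_stand = int(600 * stream.rate_hz)
    assert np.allclose(stream.data[:n_stand, 0], 1.0)
    assert np.allclose(stream.data[:n_stand, 1:], 0.0)


def test_nonwear_interval_yields_zero_counts():
    cfg = ScenarioConfig(seed=4)
    tw0 = cfg.wear_start_h * 3600.0
    schedule = [ScheduleEntry(tw0, tw0 + 1800.0, "sit"),
                ScheduleEntry(tw0 + 1800.0, tw0 + 1800.0 + 5400.0, "nonwear"),
                ScheduleEntry(tw0 + 7200.0, tw0 + 9000.0, "sit")]
    stream, _ = generate_accel_stream(cfg, 0, 0, "actigraph", "wrist", schedule)
    ep = compute_counts(stream)
    nonwear_ep = slice(30, 120)
    assert np.all(ep.vm[nonwear_ep] == 0)
    wear = detect_nonwear(ep.vm)
    assert not wear[31:119].any()
    assert wear[:30].all()


def test_overlapping_schedule_rejected():
    with pytest.raises(ValueError, match="overlap"):
        validate_schedule([ScheduleEntry(0, 100, "sit"),
                           ScheduleEntry(50, 150, "stand")])


def test_build_schedule_tiles_wear_window():
    cfg = ScenarioConfig(seed=10)
    sch = build_schedule(cfg, 3, 1)
    validate_schedule(sch)
    assert sch[0].start_t == pytest.approx(86400.0 + cfg.wear_start_h * 3600.0)
    assert sch[-1].end_t == pytest.approx(86400.0 + cfg.wear_end_h * 3600.0)
    states = {e.state for e in sch}
    assert "nonwear" in states and "walk" in states


def test_stream_deterministic_and_rate_respected():
    cfg = ScenarioConfig(seed=12)
    s1, _ = generate_accel_stream(cfg, 0, 0, "ticwatch_s2", "wrist")
    s2, _ = generate_accel_stream(cfg, 0, 0, "ticwatch_s2", "wrist")
    np.testing.assert_array_equal(s1.data, s2.data)
    assert s1.rate_hz == 25.0


# --------------------------------------------------------------------- diary
def test_zero_error_diary_equals_truth():
    cfg = ScenarioConfig(seed=13)
    _, truth = generate_accel_stream(cfg, 0, 0, "actigraph", "wrist")
    diary = generate_diary(cfg, 0, 0, truth, report_error_sd_min=0.0)
    walk = diary[diary.kind == "walk_task"].iloc[0]
    t0, t1, steps, _ = truth.walk_tasks[0]
    assert walk.start_t == t0 and walk.end_t == t1
    assert walk.steps == steps


def test_jittered_times_have_half_normal_mean_offset():
    cfg = ScenarioConfig(seed=14)
    _, truth = generate_accel_stream(cfg, 0, 0, "actigraph", "wrist")
    offs = []
    for pid in range(120):
        d = generate_diary(cfg, pid, 0, truth, report_error_sd_min=2.0)
        acts = d[d.kind == "activity"]
        for e, (_, row) in zip([x for x in truth.schedule if x.state != "nonwear"],
                               acts.iterrows()):
            offs.append(abs(row.start_t - e.start_t) / 60.0)
    # half-normal mean = sd * sqrt(2/pi)
    assert np.mean(offs) == pytest.approx(2.0 * np.sqrt(2 / np.pi), rel=0.1)
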