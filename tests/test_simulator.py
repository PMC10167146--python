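"""Generative-model guarantees: target geometry, pursuit law, event oracle."""

import numpy as np
import pytest

from pdec.binning import assign_bins
from pdec.design import TrialSpec
from pdec.events import compute_kinematics
from pdec.simulate import (SimulationConfig, TargetTrajectory, inject_saccade,
                           pupil_timecourse, simulate_trial, target_position)
from conftest import quiet_config, stationary_table


def test_target_on_circle_everywhere(traj):
    t = np.linspace(0, 30, 7001)
    x, y = target_position(t, traj)
    np.testing.assert_allclose(np.hypot(x, y), 5.4, atol=1e-9)


def test_target_start_and_quarter_turn(traj):
    assert target_position(0.0, traj) == pytest.approx((0.0, 5.4), abs=1e-12)
    quarter = (np.pi / 2) / traj.omega
    x, y = target_position(quarter, traj)
    assert (x, y) == pytest.approx((-5.4, 0.0), abs=1e-9)


def test_target_arc_length_in_one_second(traj):
    t = np.arange(0, 1.0005, 0.001)
    x, y = target_position(t, traj)
    assert np.hypot(np.diff(x), np.diff(y)).sum() == pytest.approx(6.8, abs=1e-3)


def test_identity_regime_gaze_equals_target(traj, trial, rng):
    cfg = quiet_config(gain=1.0, lag_ms=0.0)
    table, log = simulate_trial(trial, cfg, traj, rng)
    t = table.data["time_ms"].to_numpy() / 1000.0
    tx, ty = target_position(t, traj)
    np.testing.assert_allclose(table.data["xl"], tx, atol=1e-9)
    np.testing.assert_allclose(table.data["yl"], ty, atol=1e-9)
    assert len(log.saccades) == 0 and len(log.blinks) == 0


def test_gain_sets_path_speed_between_events(traj, trial, rng):
    cfg = quiet_config(gain=0.9, lag_ms=0.0)
    table, _ = simulate_trial(trial, cfg, traj, rng)
    kin = compute_kinematics(table)
    speed = kin.speed[5:-5]
    np.testing.assert_allclose(speed / 6.8, 0.9, atol=1e-6)


@pytest.mark.parametrize("lag_ms", [50, 100, 200])
def test_pure_lag_gives_chord_length_gtd(traj, trial, rng, lag_ms):
    cfg = quiet_config(gain=1.0, lag_ms=lag_ms)
    table, _ = simulate_trial(trial, cfg, traj, rng)
    t = table.data["time_ms"].to_numpy() / 1000.0
    tx, ty = target_position(t, traj)
    gtd = np.hypot(table.data["xl"] - tx, table.data["yl"] - ty)
    chord = 2 * 5.4 * np.sin(traj.omega * lag_ms / 1000.0 / 2)
    np.testing.assert_allclose(gtd, chord, atol=1e-9)


def test_injected_saccade_profile_and_micro_category():
    from pdec.simulate import GroundTruthLog
    series = stationary_table(n=3000)
    log = GroundTruthLog()
    out = inject_saccade(series, 1000, (2.0, 0.0), 30, log)
    kin = compute_kinematics(out)
    assert np.nanmax(kin.speed) > 22.0            # peak well above threshold
    assert np.nanmax(kin.speed) == pytest.approx(2 * 2.0 / 0.030, rel=0.05)
    assert log.saccades[-1].category == "unlabelled"
    out2 = inject_saccade(out, 2000, (0.5, 0.0), 30, log)
    assert log.saccades[-1].category == "micro"
    # overlap with the first saccade is rejected and logged
    before = len(log.saccades)
    out3 = inject_saccade(out2, 1010, (1.0, 0.0), 30, log)
    assert len(log.saccades) == before and len(log.rejected) == 1
    # zero displacement is the identity
    same = inject_saccade(out3, 500, (0.0, 0.0), 30, log)
    assert same.data.equals(out3.data)


def test_ground_truth_partitions_and_events_unique(traj, trial, rng):
    cfg = SimulationConfig(seed=9)
    table, log = simulate_trial(trial, cfg, traj, rng)
    assert len(log.labels) == len(table)
    # event intervals are disjoint within each class and inside the trial
    for events in ([(s.onset_ms, s.offset_ms) for s in log.saccades],
                   list(log.blinks)):
        events = sorted(events)
        assert all(a1 <= b0 for (_, a1), (b0, _) in zip(events, events[1:]))
        assert all(0 <= a < b <= trial.isi_ms for a, b in events)


def test_pupil_tonic_ordering_in_every_bin(trial):
    cfg = quiet_config(tonic_offset_mm={"single": 0.0, "low": 0.05, "high": 0.10})
    traces = {load: pupil_timecourse(trial, load, cfg)
              for load in ("single", "low", "high")}
    bins = assign_bins(np.arange(trial.isi_ms), 0)
    for k in range(1, 8):
        sel = bins == k
        assert traces["single"][sel].mean() < traces["low"][sel].mean() \
            < traces["high"][sel].mean()


def test_phasic_response_peaks_in_third_bin(trial):
    cfg = quiet_config(phasic_peak_s=1.25)
    trace = pupil_timecourse(trial, "high", cfg)
    bins = assign_bins(np.arange(trial.isi_ms), 0)
    medians = [np.median(trace[bins == k]) for k in range(1, 8)]
    assert int(np.argmax(medians)) + 1 == 3


def test_zero_phasic_amplitude_gives_flat_trace(trial):
    cfg = quiet_config(phasic_amp_mm=0.0)
    trace = pupil_timecourse(trial, "high", cfg)
    expected = cfg.pupil_baseline_mm + cfg.tonic_offset_mm["high"]
    np.testing.assert_allclose(trace, expected, atol=1e-12)


def test_saccade_storm_warning_at_noise_floor(traj, trial, rng):
    cfg = SimulationConfig(pos_noise_sd=0.5, catchup_trigger_dva=1.0, seed=1)
    with pytest.warns(UserWarning, match="noise floor"):
        simulate_trial(trial, cfg, traj, rng)
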