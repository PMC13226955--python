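"""Actuator kinematics/state machine, self-check, and the closed loop."""

from dataclasses import replace

import numpy as np
import pytest

import remloop as rl
from remloop.control import ActuatorMode, ActuatorState
from remloop.states import VigilanceState as V

PROFILE = rl.ActuatorProfile()


class TestCamKinematics:
    def test_table_values(self):
        k = rl.cam_kinematics(PROFILE)
        assert k["cam_speed_rpm"] == pytest.approx(8000 / 103)
        assert k["cam_speed_rpm"] == pytest.approx(77.7, abs=0.05)
        assert k["oscillation_freq_hz"] == pytest.approx(1.3, abs=0.01)
        assert k["accel_rad_s2"] == pytest.approx(523.6, abs=0.05)

    def test_displacement_reported_both_ways(self):
        # The cam geometry implies 5 mm; the nominal platform figure is 10 mm.
        k = rl.cam_kinematics(PROFILE)
        assert k["dpp_geometric_mm"] == pytest.approx(5.0)
        assert k["dpp_nominal_mm"] == pytest.approx(10.0)

    def test_profile_consistency_enforced(self):
        with pytest.raises(ValueError, match="target speed"):
            rl.ActuatorProfile(accel_time_s=3.0)


class TestUpdateActuator:
    def test_reaches_target_in_16_cycles(self):
        s = ActuatorState()
        for i in range(16):
            s = rl.update_actuator(s, True, 0.1, PROFILE, now=(i + 1) * 0.1)
        assert s.mode is ActuatorMode.RUNNING
        assert s.speed_rpm == pytest.approx(8000.0)

    def test_half_speed_after_half_accel_time(self):
        s = ActuatorState()
        for i in range(8):
            s = rl.update_actuator(s, True, 0.1, PROFILE, now=(i + 1) * 0.1)
        assert s.mode is ActuatorMode.ACCELERATING
        assert s.speed_rpm == pytest.approx(4000.0, rel=0.01)

    def test_low_trigger_stops_within_one_cycle(self):
        s = ActuatorState(mode=ActuatorMode.RUNNING, speed_rpm=8000.0, trigger_high=True)
        s = rl.update_actuator(s, False, 0.1, PROFILE)
        assert s.mode is ActuatorMode.IDLE and s.speed_rpm == 0.0

    def test_mode_path_idle_accel_running_idle(self):
        s = ActuatorState()
        seen = [s.mode]
        for i in range(20):
            s = rl.update_actuator(s, True, 0.1, PROFILE, now=i * 0.1)
            seen.append(s.mode)
        s = rl.update_actuator(s, False, 0.1, PROFILE)
        seen.append(s.mode)
        compressed = [seen[0]] + [m for a, m in zip(seen, seen[1:]) if m != a]
        assert compressed == [
            ActuatorMode.IDLE, ActuatorMode.ACCELERATING, ActuatorMode.RUNNING, ActuatorMode.IDLE,
        ]


class TestSelfCheck:
    def test_valid_config_passes_with_5s_actuation_burst(self, model):
        report = rl.self_check(model, PROFILE)
        assert report.passed
        events = report.actuation_test_events
        highs = [t for t, e in events if e == "TRIGGER_HIGH"]
        lows = [t for t, e in events if e == "TRIGGER_LOW"]
        assert len(highs) == 1 and len(lows) == 1
        assert lows[0] - highs[0] == pytest.approx(5.0, abs=0.2)

    def test_silent_signal_source_fails(self, model):
        silent = {
            st: rl.StateProfile(components=(), background_rms_mv=0.0, emg_rms_mv=0.0)
            for st in rl.STATE_ORDER
        }
        report = rl.self_check(replace(model, profiles=silent), PROFILE)
        assert not report.data_stream_ok
        assert not report.passed

    def test_stuck_actuator_fails_trigger_path(self, model):
        def stuck(state, trigger, dt, profile, now=0.0):
            return ActuatorState()  # never leaves idle

        report = rl.self_check(model, PROFILE, update_actuator_fn=stuck)
        assert not report.trigger_path_ok

    def test_failed_self_check_blocks_closed_loop(self, model, thresholds):
        silent = {
            st: rl.StateProfile(components=(), background_rms_mv=0.0, emg_rms_mv=0.0)
            for st in rl.STATE_ORDER
        }
        with pytest.raises(RuntimeError, match="self-check"):
            rl.run_control_loop(replace(model, profiles=silent), thresholds, duration=60.0)


class TestControlLoop:
    def test_no_rem_means_no_trigger(self, model, thresholds):
        # chain that never enters REM (and cannot start there)
        tm = np.array([[0.0, 1.0, 0.0], [0.0, 0.9, 0.1], [0.0, 0.1, 0.9]])
        m = replace(model, transition_matrix=tm)
        sess = rl.run_control_loop(m, thresholds, duration=600.0, seed=3, skip_self_check=True)
        assert not np.any(sess.trigger)
        assert np.all(sess.actuator_speed_rpm == 0.0)

    def test_ttl_high_iff_rem_decision(self, model, thresholds):
        sess = rl.run_control_loop(model, thresholds, duration=900.0, seed=4, skip_self_check=True)
        rem_decided = sess.decision == int(V.REM)
        assert np.array_equal(sess.trigger, rem_decided)

    def test_warmup_cycles_are_flagged_wake(self, model, thresholds):
        sess = rl.run_control_loop(model, thresholds, duration=300.0, seed=5, skip_self_check=True)
        assert all(f == "warmup" for f in sess.flag[:49])
        assert np.all(sess.decision[:49] == int(V.WAKE))
        assert not np.any(sess.trigger[:49])

    def test_forced_arousal_ends_bouts_within_one_epoch(self, model, thresholds):
        m = replace(model, arousal_prob=1.0)
        sess = rl.run_control_loop(m, thresholds, duration=1800.0, seed=6, skip_self_check=True)
        onsets = np.flatnonzero(np.diff(sess.trigger.astype(int)) == 1) + 1
        assert len(onsets) > 0
        for i in onsets:
            window = sess.true_state[i:i + 25]
            assert np.any(window != int(V.REM)), f"REM survived an epoch after trigger at cycle {i}"

    def test_stimulation_suppresses_rem(self, model, thresholds):
        on = rl.run_control_loop(model, thresholds, duration=3600.0, seed=7, skip_self_check=True)
        off = rl.run_control_loop(
            model, thresholds, duration=3600.0, seed=7,
            stimulation_enabled=False, skip_self_check=True,
        )
        rem_on = np.mean(on.true_state == int(V.REM))
        rem_off = np.mean(off.true_state == int(V.REM))
        assert rem_on < 0.25 * rem_off

    def test_zero_arousal_matches_unstimulated_plant_stream(self, model, thresholds):
        m = replace(model, arousal_prob=0.0)
        a = rl.run_control_loop(m, thresholds, duration=600.0, seed=8, skip_self_check=True)
        b = rl.run_control_loop(
            m, thresholds, duration=600.0, seed=8,
            stimulation_enabled=False, skip_self_check=True,
        )
        assert np.array_equal(a.true_state, b.true_state)

    def test_seeded_determinism(self, model, thresholds):
        a = rl.run_control_loop(model, thresholds, duration=300.0, seed=9, skip_self_check=True)
        b = rl.run_control_loop(model, thresholds, duration=300.0, seed=9, skip_self_check=True)
        assert np.array_equal(a.true_state, b.true_state)
        assert np.array_equal(a.decision, b.decision)
        assert np.allclose(a.r_theta_delta, b.r_theta_delta, equal_nan=True)

    def test_max_rem_seconds_termination(self, model, thresholds):
        sess = rl.run_control_loop(
            model, thresholds, duration=7200.0, seed=10,
            max_rem_seconds=2.0, stimulation_enabled=False, skip_self_check=True,
        )
        assert sess.termination == "max_rem_seconds"
        assert sess.rem_seconds() == pytest.approx(2.0, abs=0.11)
        assert len(sess) < 72000

    def test_arousal_decline_weakens_suppression_over_time(self, model, thresholds):
        """With efficacy decaying under REM pressure, late-session REM
        occupancy exceeds early-session occupancy, yet overall suppression
        persists (fold > 1 against the unstimulated run)."""
        m = replace(model, arousal_prob=1.0)
        sess = rl.run_control_loop(
            m, thresholds, duration=7200.0, seed=12,
            arousal_decline_per_hour=1.0, skip_self_check=True,
        )
        half = len(sess) // 2
        rem_early = np.mean(sess.true_state[:half] == int(V.REM))
        rem_late = np.mean(sess.true_state[half:] == int(V.REM))
        assert rem_late > rem_early
        off = rl.run_control_loop(
            m, thresholds, duration=7200.0, seed=12,
            stimulation_enabled=False, skip_self_check=True,
        )
        rem_off = np.mean(off.true_state == int(V.REM))
        assert np.mean(sess.true_state == int(V.REM)) < rem_off

    def test_session_log_round_trip(self, model, thresholds, tmp_path):
        sess = rl.run_control_loop(model, thresholds, duration=300.0, seed=13, skip_self_check=True)
        sess.write(tmp_path)
        assert (tmp_path / "session.csv").exists()
        assert (tmp_path / "events.csv").exists()
        df = sess.to_frame()
        assert len(df) == len(sess)
        assert np.all(np.diff(df["time_s"]) > 0)  # monotone timestamps
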