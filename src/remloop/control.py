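"""Closed-loop REM deprivation engine with a simulated actuator.

The control loop runs on a fixed 100 ms virtual tick (simulated time, so a
24 h session executes in about a minute of wall time). Each cycle:

1. the virtual mouse advances (Markov step at 2.5 s epoch boundaries,
   per-cycle arousal check while the platform moves),
2. 100 ms of EEG/EMG is synthesized (plus motion artifact while the
   actuator is not idle),
3. the 5 s sliding window advances and the spectral features are
   classified against the calibrated thresholds,
4. the TTL trigger goes high if and only if the decision is REM, within
   the same cycle,
5. the actuator state machine integrates the trigger: a linear velocity
   ramp at the profile's acceleration up to the target speed, immediate
   stop on a low trigger.

On the real device the per-cycle computation takes ~20 ms against the
100 ms budget and detection-to-TTL latency is below 1 ms; those are
hardware figures, not simulated here.

The actuator kinematics follow the cam drive: the motor (velocity mode)
turns an elliptical cam through a gear reduction, one platform oscillation
per cam revolution, with peak-to-peak displacement approximated by the
difference of the cam's major and minor axes. Note the geometric estimate
(15 mm − 10 mm = 5 mm) and the nominal measured displacement (10 mm)
disagree in the source hardware description; both are reported side by side.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .calibration import Thresholds
from .classify import Decision, classify, epochize
from .spectral import FS, N_FFT, STEP_S, WINDOW_S, SlidingWindow, features_from_window
from .states import STATE_ORDER, Hypnogram, VigilanceState
from .synthetic import AnimalModel, EEGSynthesizer, stationary_distribution, step_plant

RPM_TO_RAD_S = 2.0 * np.pi / 60.0


@dataclass(frozen=True)
class ActuatorProfile:
    """Motor, transmission and cam geometry of the shaking platform."""

    motor_rated_speed_rpm: float = 43_200.0
    target_speed_rpm: float = 8_000.0
    gear_ratio: float = 103.0
    accel_rad_s2: float = 523.6
    accel_time_s: float = 1.6
    cam_major_mm: float = 15.0
    cam_minor_mm: float = 10.0
    nominal_dpp_mm: float = 10.0

    def __post_init__(self) -> None:
        if self.gear_ratio <= 0:
            raise ValueError("gear_ratio must be positive")
        if self.target_speed_rpm > self.motor_rated_speed_rpm:
            raise ValueError("target speed exceeds rated motor speed")
        target_rad_s = self.target_speed_rpm * RPM_TO_RAD_S
        if abs(self.accel_time_s * self.accel_rad_s2 - target_rad_s) > 0.01 * target_rad_s:
            raise ValueError("accel_time x accel must reach the target speed (±1 %)")


def cam_kinematics(profile: ActuatorProfile) -> dict[str, float]:
    """Derived actuation figures from the profile.

    Returns cam speed (rpm), platform oscillation frequency (Hz, one cycle
    per cam revolution), peak-to-peak displacement (mm) from the cam
    geometry alongside the nominal value, and the motor acceleration
    (rad/s^2) implied by the target speed and acceleration time.
    """
    cam_speed = profile.target_speed_rpm / profile.gear_ratio
    return {
        "cam_speed_rpm": cam_speed,
        "oscillation_freq_hz": cam_speed / 60.0,
        "dpp_geometric_mm": profile.cam_major_mm - profile.cam_minor_mm,
        "dpp_nominal_mm": profile.nominal_dpp_mm,
        "accel_rad_s2": profile.target_speed_rpm * RPM_TO_RAD_S / profile.accel_time_s,
    }


class ActuatorMode(str, Enum):
    IDLE = "idle"
    ACCELERATING = "accelerating"
    RUNNING = "running"
    STOPPING = "stopping"  # unused by the default profile: stop completes within one cycle


@dataclass(frozen=True)
class ActuatorState:
    mode: ActuatorMode = ActuatorMode.IDLE
    speed_rpm: float = 0.0
    trigger_high: bool = False
    since: float = 0.0

    @property
    def moving(self) -> bool:
        return self.speed_rpm > 0.0


def update_actuator(
    state: ActuatorState,
    trigger_high: bool,
    dt: float,
    profile: ActuatorProfile,
    now: float = 0.0,
) -> ActuatorState:
    """Advance the actuator state machine by one control interval.

    High trigger: ramp speed linearly at the profile acceleration until the
    target, then hold (RUNNING). Low trigger: motor output ceases within the
    cycle (speed 0, IDLE).
    """
    if not trigger_high:
        if state.mode is ActuatorMode.IDLE:
            return replace(state, trigger_high=False)
        return ActuatorState(mode=ActuatorMode.IDLE, speed_rpm=0.0, trigger_high=False, since=now)
    step_rpm = profile.accel_rad_s2 * dt / RPM_TO_RAD_S
    speed = min(profile.target_speed_rpm, state.speed_rpm + step_rpm)
    mode = ActuatorMode.RUNNING if speed >= profile.target_speed_rpm else ActuatorMode.ACCELERATING
    since = state.since if state.mode is not ActuatorMode.IDLE else now
    return ActuatorState(mode=mode, speed_rpm=speed, trigger_high=True, since=since)


@dataclass
class ControlSession:
    """Time-aligned per-cycle log of one closed-loop run."""

    time_s: np.ndarray
    r_theta_delta: np.ndarray
    r_hf: np.ndarray
    decision: np.ndarray          # state codes
    flag: np.ndarray              # '', 'warmup', 'undefined'
    trigger: np.ndarray           # bool
    actuator_mode: np.ndarray
    actuator_speed_rpm: np.ndarray
    true_state: np.ndarray        # plant ground truth, state codes
    events: list[tuple[float, str]]
    config: dict
    termination: str = "duration"
    step_s: float = STEP_S
    epoch_duration: float = 2.5

    def __len__(self) -> int:
        return int(self.time_s.size)

    def decisions(self) -> list[Decision]:
        return [
            Decision(state=VigilanceState(int(s)), end_time=float(t), flag=str(f))
            for s, t, f in zip(self.decision, self.time_s, self.flag)
        ]

    def predicted_hypnogram(self) -> Hypnogram:
        """Majority-vote aggregation of the decision stream to 2.5 s epochs."""
        return epochize(self.decisions(), epoch_duration=self.epoch_duration, step_s=self.step_s)

    def true_hypnogram(self) -> Hypnogram:
        """Ground-truth plant state sampled at epoch resolution.

        The plant state at the last cycle of each epoch is the epoch label
        (transitions happen at epoch boundaries; mid-epoch arousals make the
        label reflect where the epoch ended up).
        """
        per_epoch = int(round(self.epoch_duration / self.step_s))
        n_epochs = len(self) // per_epoch
        # Majority state within the epoch is the honest ground-truth label.
        labels = np.empty(n_epochs, dtype=np.int8)
        for i in range(n_epochs):
            chunk = self.true_state[i * per_epoch:(i + 1) * per_epoch]
            vals, counts = np.unique(chunk, return_counts=True)
            labels[i] = vals[np.argmax(counts)]
        return Hypnogram(labels=labels, epoch_duration=self.epoch_duration)

    def rem_seconds(self) -> float:
        return float(np.sum(self.true_state == int(VigilanceState.REM)) * self.step_s)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time_s,
                "r_theta_delta": self.r_theta_delta,
                "r_hf": self.r_hf,
                "decision_code": self.decision.astype(int),
                "flag": self.flag,
                "trigger": self.trigger.astype(int),
                "actuator_mode": self.actuator_mode,
                "actuator_speed_rpm": self.actuator_speed_rpm,
                "true_state_code": self.true_state.astype(int),
            }
        )

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(out / "session.csv", index=False)
        pd.DataFrame(self.events, columns=["time_s", "event"]).to_csv(
            out / "events.csv", index=False
        )


@dataclass(frozen=True)
class CheckReport:
    """Result of the pre-run self-check."""

    data_stream_ok: bool
    feature_pipeline_ok: bool
    trigger_path_ok: bool
    actuation_test_events: list[tuple[float, str]] = field(default_factory=list)
    messages: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return self.data_stream_ok and self.feature_pipeline_ok and self.trigger_path_ok


def self_check(
    animal: AnimalModel,
    profile: ActuatorProfile,
    fs: float = FS,
    actuation_test_s: float = 5.0,
    update_actuator_fn: Callable[..., ActuatorState] = update_actuator,
) -> CheckReport:
    """Verify the signal source, feature pipeline and trigger path.

    Runs a short actuation burst (~5 s of high trigger followed by release)
    and checks that the actuator leaves idle and returns to it. A custom
    ``update_actuator_fn`` can be injected to test fault detection.
    """
    messages: list[str] = []
    synth = EEGSynthesizer(animal, fs=fs, rng=0)
    eeg, _ = synth.next_block(VigilanceState.NREM, int(fs * WINDOW_S))
    data_ok = bool(np.std(eeg) > 0)
    if not data_ok:
        messages.append("signal source produced constant samples")

    feature_ok = False
    if data_ok:
        feats = features_from_window(eeg, fs=fs)
        feature_ok = bool(
            not feats.undefined
            and np.isfinite(feats.r_theta_delta)
            and np.isfinite(feats.r_hf)
        )
    if not feature_ok:
        messages.append("feature pipeline did not return finite features")

    events: list[tuple[float, str]] = []
    state = ActuatorState()
    n_cycles = int(round(actuation_test_s / STEP_S))
    left_idle = False
    t = 0.0
    events.append((t, "TRIGGER_HIGH"))
    for i in range(n_cycles):
        t = (i + 1) * STEP_S
        prev_mode = state.mode
        state = update_actuator_fn(state, True, STEP_S, profile, now=t)
        if state.mode is not ActuatorMode.IDLE:
            left_idle = True
        if prev_mode is not ActuatorMode.RUNNING and state.mode is ActuatorMode.RUNNING:
            events.append((t, "MOTOR_RUNNING"))
    events.append((t, "TRIGGER_LOW"))
    state = update_actuator_fn(state, False, STEP_S, profile, now=t + STEP_S)
    returned_idle = state.mode is ActuatorMode.IDLE and state.speed_rpm == 0.0
    trigger_ok = left_idle and returned_idle
    if not trigger_ok:
        messages.append("actuator did not toggle on the trigger path")

    return CheckReport(
        data_stream_ok=data_ok,
        feature_pipeline_ok=feature_ok,
        trigger_path_ok=trigger_ok,
        actuation_test_events=events,
        messages=messages,
    )


def run_control_loop(
    animal: AnimalModel,
    thresholds: Thresholds,
    duration: float,
    seed: int = 0,
    profile: ActuatorProfile | None = None,
    fs: float = FS,
    epoch_duration: float = 2.5,
    stimulation_enabled: bool = True,
    max_rem_seconds: float | None = None,
    arousal_decline_per_hour: float = 0.0,
    skip_self_check: bool = False,
) -> ControlSession:
    """Simulate one closed-loop REM deprivation session.

    Per 100 ms cycle: plant step -> signal synthesis (+ artifact while the
    platform moves) -> window push -> PSD -> features -> classification ->
    TTL trigger (high iff the decision is REM) -> actuator update. The
    first 5 s are warm-up (Wake decisions, no actuation). Deterministic
    given the seed: plant and signal randomness run on independent child
    streams of the seed.

    ``arousal_decline_per_hour`` optionally reduces the effective arousal
    probability linearly with accumulated REM pressure (hours of session
    time), emulating attenuated stimulus efficacy during prolonged
    deprivation; disabled (0) by default. ``max_rem_seconds`` is an optional
    early-termination condition on cumulative REM time.
    """
    profile = profile or ActuatorProfile()
    if not skip_self_check:
        report = self_check(animal, profile, fs=fs)
        if not report.passed:
            raise RuntimeError(f"self-check failed: {report.messages}")

    ss = np.random.SeedSequence(seed)
    plant_rng, signal_rng = [np.random.default_rng(s) for s in ss.spawn(2)]
    synth = EEGSynthesizer(animal, fs=fs, rng=signal_rng)
    window = SlidingWindow(fs=fs, window_s=WINDOW_S, step_s=STEP_S)
    n_step = window.n_step
    cycles_per_epoch = int(round(epoch_duration / STEP_S))
    n_cycles = int(round(duration / STEP_S))

    # Initial plant state from the chain's stationary distribution.
    pi = stationary_distribution(animal.transition_matrix)
    state = STATE_ORDER[int(plant_rng.choice(3, p=pi))]

    t_arr = np.empty(n_cycles)
    r_td = np.full(n_cycles, np.nan)
    r_hf = np.full(n_cycles, np.nan)
    dec = np.empty(n_cycles, dtype=np.int8)
    flags = np.empty(n_cycles, dtype=object)
    trig = np.zeros(n_cycles, dtype=bool)
    act_mode = np.empty(n_cycles, dtype=object)
    act_speed = np.empty(n_cycles)
    true_st = np.empty(n_cycles, dtype=np.int8)
    events: list[tuple[float, str]] = []

    actuator = ActuatorState()
    rem_seconds = 0.0
    termination = "duration"
    base_arousal = animal.arousal_prob

    n_done = n_cycles
    for i in range(n_cycles):
        t = (i + 1) * STEP_S
        boundary = (i % cycles_per_epoch == 0) and i > 0
        if arousal_decline_per_hour > 0.0:
            eff = max(0.0, base_arousal - arousal_decline_per_hour * t / 3600.0)
            animal = replace(animal, arousal_prob=eff) if eff != animal.arousal_prob else animal
        state = step_plant(
            state,
            stimulating=actuator.moving and stimulation_enabled,
            model=animal,
            rng=plant_rng,
            epoch_boundary=boundary,
        )
        eeg, _ = synth.next_block(state, n_step)
        if actuator.moving:
            eeg = eeg + synth.artifact_block(n_step)
        eeg = np.clip(eeg, -animal.clip_mv, animal.clip_mv)
        win = window.push(eeg)

        if window.full:
            feats = features_from_window(win, fs=fs, n_fft=N_FFT, end_time=t)
            decision = classify(feats, thresholds)
            r_td[i], r_hf[i] = feats.r_theta_delta, feats.r_hf
        else:
            decision = Decision(state=VigilanceState.WAKE, end_time=t, flag="warmup")

        trigger_high = stimulation_enabled and decision.state is VigilanceState.REM
        if trigger_high and not actuator.trigger_high:
            events.append((t, "TRIGGER_HIGH"))
        if not trigger_high and actuator.trigger_high:
            events.append((t, "TRIGGER_LOW"))
        prev_mode = actuator.mode
        actuator = update_actuator(actuator, trigger_high, STEP_S, profile, now=t)
        if prev_mode is not ActuatorMode.RUNNING and actuator.mode is ActuatorMode.RUNNING:
            events.append((t, "MOTOR_RUNNING"))
        if prev_mode is not ActuatorMode.IDLE and actuator.mode is ActuatorMode.IDLE:
            events.append((t, "MOTOR_IDLE"))

        t_arr[i] = t
        dec[i] = int(decision.state)
        flags[i] = decision.flag
        trig[i] = trigger_high
        act_mode[i] = actuator.mode.value
        act_speed[i] = actuator.speed_rpm
        true_st[i] = int(state)
        if state is VigilanceState.REM:
            rem_seconds += STEP_S
        if max_rem_seconds is not None and rem_seconds >= max_rem_seconds:
            termination = "max_rem_seconds"
            n_done = i + 1
            events.append((t, "TERMINATED_MAX_REM"))
            break

    sl = slice(0, n_done)
    return ControlSession(
        time_s=t_arr[sl],
        r_theta_delta=r_td[sl],
        r_hf=r_hf[sl],
        decision=dec[sl],
        flag=flags[sl],
        trigger=trig[sl],
        actuator_mode=act_mode[sl],
        actuator_speed_rpm=act_speed[sl],
        true_state=true_st[sl],
        events=events,
        config={
            "seed": seed,
            "duration_s": duration,
            "fs": fs,
            "epoch_s": epoch_duration,
            "stimulation_enabled": stimulation_enabled,
            "arousal_prob": base_arousal,
            "arousal_decline_per_hour": arousal_decline_per_hour,
            "animal_id": animal.animal_id,
        },
        termination=termination,
        epoch_duration=epoch_duration,
    )
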