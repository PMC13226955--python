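"""Synthetic rodent EEG/EMG with a ground-truth hypnogram.

This module is the "virtual mouse": a three-state Markov chain over
(REM, Wake, NREM) at 2.5 s epoch resolution drives a state-dependent signal
synthesizer, and a probabilistic arousal rule lets platform stimulation
terminate REM bouts.

Signal model
------------
Each state's EEG is a sum of narrowband oscillatory components (band-pass
filtered white noise, parameterised by centre frequency, bandwidth and RMS
amplitude in mV) on top of a 1/f pink background. REM is theta-dominant
(~6.5 Hz), NREM delta-dominant (~2 Hz), and Wake carries an additional
broadband 90–200 Hz component. EMG is white noise with a per-state RMS
(atonia in REM, high tone in Wake). All filters keep their internal state
across blocks, so signals are spectrally stationary within a state and
continuous across the 100 ms blocks used by the real-time loop.

Platform motion adds a broadband 90–200 Hz artifact to the EEG, which the
downstream classifier reads as wakefulness — the same fail-safe behaviour
movement artifacts produce on real recordings.

Samples are clipped to the ±5 mV ADC range; clip events are counted on the
returned traces.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import yaml
from scipy import signal as sps

from .states import STATE_INDEX, STATE_ORDER, Hypnogram, SignalTrace, VigilanceState

#: ADC full scale, mV.
CLIP_MV = 5.0

# 1/f (pink) shaping filter, a standard low-order IIR approximation whose
# magnitude follows f^(-1/2) (power ~ 1/f) over roughly three decades below
# Nyquist — at fs = 1 kHz that covers the full 0.5–500 Hz analysis band.
_PINK_B = np.array([0.049922035, -0.095993537, 0.050612699, -0.004408786])
_PINK_A = np.array([1.0, -2.494956002, 2.017265875, -0.522189400])


class BandComponent(NamedTuple):
    """One narrowband oscillator: centre (Hz), bandwidth (Hz), RMS amplitude (mV)."""

    center_hz: float
    bandwidth_hz: float
    amplitude_mv: float


@dataclass(frozen=True)
class StateProfile:
    """Spectral content of one vigilance state."""

    components: tuple[BandComponent, ...]
    background_rms_mv: float
    emg_rms_mv: float

    def max_frequency(self) -> float:
        if not self.components:
            return 0.0
        return max(c.center_hz + c.bandwidth_hz / 2 for c in self.components)


@dataclass(frozen=True)
class AnimalModel:
    """Generative parameters of one synthetic animal.

    ``transition_matrix`` is row-stochastic over (REM, Wake, NREM), applied
    once per 2.5 s epoch. ``arousal_prob`` is the per-100 ms-cycle
    probability that ongoing platform motion terminates a REM bout — the
    stimulus effect is probabilistic, not deterministic. ``artifact_hf_gain_mv``
    is the RMS of the broadband 90–200 Hz artifact added while the platform
    moves.
    """

    profiles: dict[VigilanceState, StateProfile]
    transition_matrix: np.ndarray
    arousal_prob: float = 0.3
    artifact_hf_gain_mv: float = 0.2
    clip_mv: float = CLIP_MV
    animal_id: str = "synthetic-01"

    def __post_init__(self) -> None:
        tm = np.asarray(self.transition_matrix, dtype=float)
        if tm.shape != (3, 3):
            raise ValueError("transition_matrix must be 3x3 over (REM, Wake, NREM)")
        if np.any(tm < 0):
            raise ValueError("transition probabilities must be non-negative")
        if not np.allclose(tm.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition_matrix rows must sum to 1 (±1e-9)")
        if not 0.0 <= self.arousal_prob <= 1.0:
            raise ValueError("arousal_prob must lie in [0, 1]")
        if self.artifact_hf_gain_mv < 0:
            raise ValueError("artifact_hf_gain_mv must be >= 0")
        for st in STATE_ORDER:
            if st not in self.profiles:
                raise ValueError(f"missing profile for state {st.name}")
            prof = self.profiles[st]
            if prof.background_rms_mv < 0 or prof.emg_rms_mv < 0:
                raise ValueError("amplitudes must be >= 0")
            if any(c.amplitude_mv < 0 for c in prof.components):
                raise ValueError("amplitudes must be >= 0")
        object.__setattr__(self, "transition_matrix", tm)

    def max_frequency(self) -> float:
        return max(self.profiles[st].max_frequency() for st in STATE_ORDER)

    # --- serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "animal_id": self.animal_id,
            "arousal_prob": self.arousal_prob,
            "artifact_hf_gain_mv": self.artifact_hf_gain_mv,
            "clip_mv": self.clip_mv,
            "transition_matrix": self.transition_matrix.tolist(),
            "profiles": {
                st.name: {
                    "components": [list(c) for c in self.profiles[st].components],
                    "background_rms_mv": self.profiles[st].background_rms_mv,
                    "emg_rms_mv": self.profiles[st].emg_rms_mv,
                }
                for st in STATE_ORDER
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AnimalModel":
        profiles = {
            VigilanceState[name]: StateProfile(
                components=tuple(BandComponent(*c) for c in p["components"]),
                background_rms_mv=float(p["background_rms_mv"]),
                emg_rms_mv=float(p["emg_rms_mv"]),
            )
            for name, p in d["profiles"].items()
        }
        return cls(
            profiles=profiles,
            transition_matrix=np.asarray(d["transition_matrix"], dtype=float),
            arousal_prob=float(d.get("arousal_prob", 0.3)),
            artifact_hf_gain_mv=float(d.get("artifact_hf_gain_mv", 0.2)),
            clip_mv=float(d.get("clip_mv", CLIP_MV)),
            animal_id=str(d.get("animal_id", "synthetic-01")),
        )

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict())
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "AnimalModel":
        path = Path(path)
        d = yaml.safe_load(path.read_text())
        return cls.from_dict(d)

    @classmethod
    def default(cls, animal_id: str = "synthetic-01") -> "AnimalModel":
        """The reference virtual mouse.

        Stationary occupancy of the transition matrix is exactly
        (REM 7 %, Wake 45 %, NREM 48 %); mean dwell times are about
        104 s (REM), 125 s (Wake) and 130 s (NREM) at 2.5 s epochs.
        """
        tm = np.array(
            [
                [0.976, 0.021, 0.003],       # REM exits mostly to Wake
                [0.0, 0.98, 0.02],           # no direct Wake -> REM in mice
                [0.0035, 0.0156875, 0.9808125],
            ]
        )
        profiles = {
            VigilanceState.REM: StateProfile(
                components=(
                    BandComponent(6.5, 1.5, 0.25),   # theta
                    BandComponent(2.0, 1.5, 0.05),   # residual delta
                ),
                background_rms_mv=0.008,
                emg_rms_mv=0.02,                      # atonia
            ),
            VigilanceState.WAKE: StateProfile(
                components=(
                    BandComponent(6.5, 2.0, 0.10),
                    BandComponent(2.0, 1.5, 0.08),
                    BandComponent(145.0, 110.0, 0.08),  # broadband HF
                ),
                background_rms_mv=0.02,
                emg_rms_mv=0.40,
            ),
            VigilanceState.NREM: StateProfile(
                components=(
                    BandComponent(2.0, 1.5, 0.20),   # slow-wave delta
                    BandComponent(6.5, 1.5, 0.05),
                ),
                background_rms_mv=0.015,
                emg_rms_mv=0.08,
            ),
        }
        return cls(profiles=profiles, transition_matrix=tm, animal_id=animal_id)


def stationary_distribution(transition_matrix: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (left eigenvector)."""
    tm = np.asarray(transition_matrix, dtype=float)
    vals, vecs = np.linalg.eig(tm.T)
    k = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, k])
    pi = np.abs(pi)
    return pi / pi.sum()


def generate_hypnogram(
    model: AnimalModel,
    duration: float,
    epoch_duration: float = 2.5,
    seed: int | np.random.Generator = 0,
) -> Hypnogram:
    """Sample a ground-truth hypnogram from the model's Markov chain.

    The initial state is drawn from the stationary distribution so that
    occupancies are unbiased from epoch zero. Deterministic given the seed.
    """
    if duration < epoch_duration:
        raise ValueError("duration must cover at least one epoch")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n_epochs = int(duration // epoch_duration)
    tm = model.transition_matrix
    pi = stationary_distribution(tm)
    labels = np.empty(n_epochs, dtype=np.int8)
    state_idx = int(rng.choice(3, p=pi))
    cum = np.cumsum(tm, axis=1)
    u = rng.random(n_epochs)
    for i in range(n_epochs):
        labels[i] = int(STATE_ORDER[state_idx])
        state_idx = int(np.searchsorted(cum[state_idx], u[i], side="right"))
        state_idx = min(state_idx, 2)
    return Hypnogram(labels=labels, epoch_duration=epoch_duration)


def step_plant(
    current_state: VigilanceState,
    stimulating: bool,
    model: AnimalModel,
    rng: np.random.Generator,
    epoch_boundary: bool = False,
) -> VigilanceState:
    """Advance the virtual mouse by one 100 ms control cycle.

    Spontaneous transitions follow the epoch-level Markov chain and are
    applied only when ``epoch_boundary`` is set. Stimulation-induced arousal
    is evaluated every cycle: while the platform moves during REM, the bout
    terminates into Wake with probability ``model.arousal_prob`` per cycle.
    The arousal uniform is drawn on every REM cycle (used or not) so the
    random stream is identical whether or not stimulation is enabled.
    """
    state = current_state
    if epoch_boundary:
        row = model.transition_matrix[STATE_INDEX[state]]
        state = STATE_ORDER[int(rng.choice(3, p=row))]
    if state is VigilanceState.REM:
        u = rng.random()
        if stimulating and u < model.arousal_prob:
            state = VigilanceState.WAKE
    return state


class _FilteredNoise:
    """Band-limited noise with persistent filter state and calibrated RMS gain."""

    def __init__(self, sos: np.ndarray, target_rms: float):
        self.sos = sos
        self.zi = sps.sosfilt_zi(sos) * 0.0
        # Empirical gain: unit white noise through a fresh copy of the filter.
        calib_rng = np.random.default_rng(987654321)
        ref = sps.sosfilt(sos, calib_rng.standard_normal(20000))
        rms = float(np.sqrt(np.mean(ref[2000:] ** 2)))  # skip transient
        self.gain = target_rms / rms if rms > 0 else 0.0

    def step(self, white: np.ndarray) -> np.ndarray:
        out, self.zi = sps.sosfilt(self.sos, white, zi=self.zi)
        return out * self.gain


class _PinkNoise:
    """1/f background with persistent state and calibrated RMS gain."""

    def __init__(self, target_rms: float):
        self.zi = sps.lfilter_zi(_PINK_B, _PINK_A) * 0.0
        calib_rng = np.random.default_rng(123456789)
        ref = sps.lfilter(_PINK_B, _PINK_A, calib_rng.standard_normal(20000))
        rms = float(np.sqrt(np.mean(ref[2000:] ** 2)))
        self.gain = target_rms / rms if rms > 0 else 0.0

    def step(self, white: np.ndarray) -> np.ndarray:
        out, self.zi = sps.lfilter(_PINK_B, _PINK_A, white, zi=self.zi)
        return out * self.gain


def _component_sos(comp: BandComponent, fs: float) -> np.ndarray:
    lo = max(comp.center_hz - comp.bandwidth_hz / 2, 0.01)
    hi = min(comp.center_hz + comp.bandwidth_hz / 2, fs / 2 * 0.999)
    return sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")


class EEGSynthesizer:
    """Streaming state-dependent EEG/EMG source.

    Produces arbitrary-length blocks; only the active state's filters are
    fed, so brief spectral build-up after a state change mimics the gradual
    transitions of real recordings.
    """

    def __init__(self, model: AnimalModel, fs: float = 1000.0, rng: np.random.Generator | int = 0):
        if fs < 2 * model.max_frequency():
            raise ValueError("sampling rate below Nyquist limit of the model profiles")
        self.model = model
        self.fs = float(fs)
        self.rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        self._channels: dict[VigilanceState, list[_FilteredNoise]] = {}
        self._background: dict[VigilanceState, _PinkNoise] = {}
        for st in STATE_ORDER:
            prof = model.profiles[st]
            self._channels[st] = [
                _FilteredNoise(_component_sos(c, fs), c.amplitude_mv) for c in prof.components
            ]
            self._background[st] = _PinkNoise(prof.background_rms_mv)
        art_sos = sps.butter(4, [90.0, min(200.0, fs / 2 * 0.999)], btype="bandpass", fs=fs, output="sos")
        self._artifact = _FilteredNoise(art_sos, model.artifact_hf_gain_mv)
        self.n_clipped = 0

    def next_block(self, state: VigilanceState, n: int) -> tuple[np.ndarray, np.ndarray]:
        """Generate ``n`` samples of (EEG, EMG) for the given state, in mV."""
        prof = self.model.profiles[state]
        eeg = np.zeros(n)
        for chan in self._channels[state]:
            eeg += chan.step(self.rng.standard_normal(n))
        eeg += self._background[state].step(self.rng.standard_normal(n))
        emg = prof.emg_rms_mv * self.rng.standard_normal(n)
        return eeg, emg

    def artifact_block(self, n: int) -> np.ndarray:
        """Broadband 90–200 Hz motion artifact, ``n`` samples."""
        return self._artifact.step(self.rng.standard_normal(n))

    def clip(self, x: np.ndarray) -> np.ndarray:
        clipped = np.clip(x, -self.model.clip_mv, self.model.clip_mv)
        self.n_clipped += int(np.sum(np.abs(x) > self.model.clip_mv))
        return clipped


def synthesize_signals(
    hypnogram: Hypnogram,
    model: AnimalModel,
    fs: float = 1000.0,
    seed: int | np.random.Generator = 0,
) -> tuple[SignalTrace, SignalTrace]:
    """Render a hypnogram into continuous EEG and EMG traces.

    Deterministic given the seed. Samples are clipped to the ADC range and
    clip counts recorded on the returned traces.
    """
    if len(hypnogram) == 0:
        raise ValueError("hypnogram is empty")
    synth = EEGSynthesizer(model, fs=fs, rng=seed)
    n_epoch = int(round(hypnogram.epoch_duration * fs))
    eeg_parts, emg_parts = [], []
    for state in hypnogram.states():
        e, m = synth.next_block(state, n_epoch)
        eeg_parts.append(e)
        emg_parts.append(m)
    eeg = synth.clip(np.concatenate(eeg_parts))
    n_clip_eeg = synth.n_clipped
    emg = synth.clip(np.concatenate(emg_parts))
    return (
        SignalTrace(samples=eeg, fs=fs, channel="EEG", start_time=hypnogram.start_time,
                    n_clipped=n_clip_eeg),
        SignalTrace(samples=emg, fs=fs, channel="EMG", start_time=hypnogram.start_time,
                    n_clipped=synth.n_clipped - n_clip_eeg),
    )


def inject_motion_artifact(
    trace: SignalTrace,
    intervals: Sequence[tuple[float, float]],
    model: AnimalModel,
    rng: np.random.Generator | int = 0,
) -> SignalTrace:
    """Add broadband 90–200 Hz artifact to a trace inside the given intervals.

    Intervals are (start_s, end_s) relative to the trace start; they must be
    non-overlapping and correctly ordered. Samples outside the intervals are
    untouched.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    ivs = sorted((float(a), float(b)) for a, b in intervals)
    last_end = -np.inf
    for a, b in ivs:
        if b <= a:
            raise ValueError(f"inverted interval ({a}, {b})")
        if a < last_end:
            raise ValueError("overlapping artifact intervals")
        if a < 0 or b > trace.duration + 1e-9:
            raise ValueError(f"interval ({a}, {b}) outside trace duration {trace.duration}")
        last_end = b
    out = trace.samples.copy()
    sos = sps.butter(4, [90.0, min(200.0, trace.fs / 2 * 0.999)], btype="bandpass",
                     fs=trace.fs, output="sos")
    comp = _FilteredNoise(sos, model.artifact_hf_gain_mv)
    for a, b in ivs:
        i0, i1 = int(round(a * trace.fs)), int(round(b * trace.fs))
        out[i0:i1] += comp.step(rng.standard_normal(i1 - i0))
    n_extra = int(np.sum(np.abs(out) > model.clip_mv))
    out = np.clip(out, -model.clip_mv, model.clip_mv)
    return SignalTrace(samples=out, fs=trace.fs, channel=trace.channel,
                       start_time=trace.start_time, n_clipped=trace.n_clipped + n_extra)
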