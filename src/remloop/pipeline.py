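"""End-to-end conveniences tying generation, calibration and the loop together.

The offline path mirrors the experimental workflow: record (synthesize) a
labeled baseline without actuation, extract one feature pair per 2.5 s
epoch, estimate per-animal thresholds, validate them on a held-out session,
then run the closed loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import (
    StateFeatureStats,
    Thresholds,
    estimate_thresholds,
    state_feature_stats,
    validate_thresholds,
)
from .spectral import FS, N_FFT, WINDOW_S, SpectralFeatures, features_from_window
from .states import Hypnogram, SignalTrace
from .synthetic import AnimalModel, generate_hypnogram, synthesize_signals


def epoch_features(
    eeg: SignalTrace | np.ndarray,
    fs: float = FS,
    epoch_duration: float = 2.5,
    n_fft: int = N_FFT,
) -> list[SpectralFeatures]:
    """One feature pair per epoch, from the 5 s window ending at epoch end.

    Early epochs whose end precedes the first full window use the first 5 s
    of data (the online system would flag these as warm-up).
    """
    samples = eeg.samples if isinstance(eeg, SignalTrace) else np.asarray(eeg, float)
    n_window = int(round(WINDOW_S * fs))
    n_epoch = int(round(epoch_duration * fs))
    n_epochs = len(samples) // n_epoch
    if len(samples) < n_window:
        raise ValueError("recording shorter than one analysis window")
    feats = []
    for i in range(n_epochs):
        end = max((i + 1) * n_epoch, n_window)
        win = samples[end - n_window:end]
        feats.append(features_from_window(win, fs=fs, n_fft=n_fft, end_time=end / fs))
    return feats


@dataclass(frozen=True)
class BaselineRecording:
    """A labeled synthetic baseline session."""

    hypnogram: Hypnogram
    eeg: SignalTrace
    emg: SignalTrace
    features: list[SpectralFeatures]


def record_baseline(
    model: AnimalModel,
    duration: float,
    seed: int = 0,
    fs: float = FS,
    epoch_duration: float = 2.5,
) -> BaselineRecording:
    """Synthesize an unstimulated labeled session with per-epoch features."""
    hyp = generate_hypnogram(model, duration, epoch_duration=epoch_duration, seed=seed)
    eeg, emg = synthesize_signals(hyp, model, fs=fs, seed=seed + 1)
    feats = epoch_features(eeg, fs=fs, epoch_duration=epoch_duration)
    return BaselineRecording(hypnogram=hyp, eeg=eeg, emg=emg, features=feats)


def calibrate(
    baseline: BaselineRecording, animal_id: str = ""
) -> tuple[Thresholds, StateFeatureStats]:
    """Thresholds from a labeled baseline recording."""
    stats = state_feature_stats(baseline.features, baseline.hypnogram)
    thr = estimate_thresholds(stats, animal_id=animal_id)
    return thr, stats


def calibrate_and_validate(
    model: AnimalModel,
    baseline_duration: float = 4 * 3600.0,
    validation_duration: float = 3600.0,
    seed: int = 0,
    fs: float = FS,
):
    """Baseline calibration followed by a held-out validation session.

    Returns (thresholds, validation gate). The validation session uses an
    independent seed stream from the calibration baseline.
    """
    base = record_baseline(model, baseline_duration, seed=seed, fs=fs)
    thr, _ = calibrate(base, animal_id=model.animal_id)
    held_out = record_baseline(model, validation_duration, seed=seed + 10_000, fs=fs)
    gate = validate_thresholds(held_out.features, held_out.hypnogram, thr)
    return thr, gate
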