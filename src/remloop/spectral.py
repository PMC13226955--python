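"""Sliding-window FFT band-power features for real-time sleep staging.

The online pipeline analyses a 5 s window (5000 samples at 1 kHz) that
advances in 100 ms steps, giving a 98 % overlap between consecutive windows.
Each window is Hanning-tapered, zero-padded to 10,000 points (0.1 Hz bins)
and reduced to two ratios:

* ``r_theta_delta`` — theta (4–8 Hz) over delta (0.5–4 Hz) band power;
  elevated during REM sleep.
* ``r_hf`` — 90–200 Hz power as a fraction of total 0.5–500 Hz power;
  elevated during wakefulness and movement artifacts.

Band sums are Riemann sums sum(p(fk) * df) over half-open intervals
[f_lo, f_hi); the terminal Nyquist bin is included when f_hi equals fs/2 so
the total band covers the full recorded bandwidth. The DC bin never enters
any band (the analog front end is high-passed at 0.5 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Analysis window length in seconds.
WINDOW_S = 5.0
#: Control-loop step in seconds (100 ms).
STEP_S = 0.1
#: Default sampling rate, Hz.
FS = 1000.0
#: FFT length after zero-padding.
N_FFT = 10_000

#: Classification bands, Hz.
DELTA_BAND = (0.5, 4.0)
THETA_BAND = (4.0, 8.0)
HF_BAND = (90.0, 200.0)
TOTAL_BAND = (0.5, 500.0)


@dataclass(frozen=True)
class PowerSpectrum:
    """One-sided periodogram on the fixed 0.1 Hz grid.

    ``psd`` is a power spectral density in mV^2/Hz so that band powers are
    ``sum(psd * df)``. The grid has ``n_fft/2 + 1`` bins from 0 to fs/2.
    """

    freqs: np.ndarray
    psd: np.ndarray
    df: float

    def __post_init__(self) -> None:
        if self.freqs.shape != self.psd.shape:
            raise ValueError("freqs and psd must have matching shapes")


@dataclass(frozen=True)
class SpectralFeatures:
    """The classifier's input: the (r_theta_delta, r_hf) pair for one window.

    ``undefined`` is set when a denominator band carries no power; such
    features are treated as Wake downstream (fail-safe: no actuation is
    driven by degenerate spectra).
    """

    r_theta_delta: float
    r_hf: float
    end_time: float = float("nan")
    undefined: bool = False


class SlidingWindow:
    """Fixed 5000-sample ring buffer advanced in 100-sample blocks.

    Mirrors the acquisition contract: every 100 ms a block of 100 new
    samples replaces the oldest 100, so consecutive windows share
    4900/5000 = 98 % of their samples. The window is not "full" until
    5 s of data have been pushed; decisions before that are warm-up.
    """

    def __init__(self, fs: float = FS, window_s: float = WINDOW_S, step_s: float = STEP_S):
        self.fs = float(fs)
        self.window_s = float(window_s)
        self.step_s = float(step_s)
        self.n_window = int(round(fs * window_s))
        self.n_step = int(round(fs * step_s))
        if self.n_window % self.n_step:
            raise ValueError("window length must be a multiple of the step")
        self._buf = np.zeros(self.n_window)
        self._filled = 0
        self.end_time = 0.0

    @property
    def full(self) -> bool:
        return self._filled >= self.n_window

    @property
    def overlap_fraction(self) -> float:
        """Shared fraction between consecutive windows: (N - step)/N."""
        return (self.n_window - self.n_step) / self.n_window

    def push(self, block: np.ndarray) -> np.ndarray:
        """Append one 100 ms block, discard the oldest, return the window."""
        block = np.asarray(block, dtype=np.float64)
        if block.shape != (self.n_step,):
            raise ValueError(
                f"push expects exactly {self.n_step} samples per step, got {block.shape}"
            )
        self._buf = np.concatenate([self._buf[self.n_step:], block])
        self._filled = min(self._filled + self.n_step, self.n_window)
        self.end_time += self.step_s
        return self._buf

    @property
    def samples(self) -> np.ndarray:
        return self._buf.copy()


def compute_psd(window: np.ndarray, fs: float = FS, n_fft: int = N_FFT) -> PowerSpectrum:
    """One-sided periodogram of a Hanning-tapered, zero-padded window.

    Density scaling with coherent window-power correction; since the two
    downstream features are ratios of band powers any consistent scaling is
    equivalent, but density scaling keeps ``sum(psd*df)`` physically
    meaningful (mV^2).
    """
    window = np.asarray(window, dtype=np.float64)
    if window.ndim != 1:
        raise ValueError("window must be one-dimensional")
    if not np.all(np.isfinite(window)):
        raise ValueError("window contains non-finite samples")
    n = window.size
    if n_fft < n:
        raise ValueError("n_fft must be at least the window length")
    taper = np.hanning(n)
    spec = np.fft.rfft(window * taper, n_fft)
    # One-sided density: double everything except DC and Nyquist.
    scale = 1.0 / (fs * np.sum(taper**2))
    psd = (np.abs(spec) ** 2) * scale
    psd[1:-1] *= 2.0
    df = fs / n_fft
    freqs = np.arange(psd.size) * df
    return PowerSpectrum(freqs=freqs, psd=psd, df=df)


def band_power(spectrum: PowerSpectrum, f_lo: float, f_hi: float) -> float:
    """Riemann band power ``sum(p(fk) * df)`` over ``[f_lo, f_hi)``.

    The half-open convention prevents double-counting the shared 4 Hz edge
    between the delta and theta bands; the Nyquist bin is included when
    ``f_hi`` reaches it so the total band spans the recorded bandwidth.
    The 0 Hz bin is excluded from every band.
    """
    if f_lo < 0 or f_hi > spectrum.freqs[-1] + 1e-9 or f_lo >= f_hi:
        raise ValueError(f"invalid band [{f_lo}, {f_hi}]")
    f = spectrum.freqs
    tol = spectrum.df * 1e-6
    mask = (f >= f_lo - tol) & (f < f_hi - tol)
    if f_hi >= f[-1] - tol:  # terminal Nyquist bin
        mask[-1] = True
    mask[0] = False  # DC never counts
    return float(np.sum(spectrum.psd[mask]) * spectrum.df)


def extract_features(spectrum: PowerSpectrum, end_time: float = float("nan")) -> SpectralFeatures:
    """Reduce a spectrum to the (theta/delta, high-frequency) ratio pair.

    Degenerate denominators (no delta power or no total power) yield a
    flagged sentinel feature which the classifier maps to Wake.
    """
    p_delta = band_power(spectrum, *DELTA_BAND)
    p_theta = band_power(spectrum, *THETA_BAND)
    p_hf = band_power(spectrum, *HF_BAND)
    p_total = band_power(spectrum, *TOTAL_BAND)
    if p_delta <= 0.0 or p_total <= 0.0:
        return SpectralFeatures(
            r_theta_delta=float("nan"), r_hf=float("nan"), end_time=end_time, undefined=True
        )
    return SpectralFeatures(
        r_theta_delta=p_theta / p_delta,
        r_hf=p_hf / p_total,
        end_time=end_time,
        undefined=False,
    )


def features_from_window(
    window: np.ndarray, fs: float = FS, n_fft: int = N_FFT, end_time: float = float("nan")
) -> SpectralFeatures:
    """Convenience: PSD + feature extraction in one call."""
    return extract_features(compute_psd(window, fs=fs, n_fft=n_fft), end_time=end_time)
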