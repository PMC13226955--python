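"""Offline evaluation: staging accuracy and REM-suppression efficacy.

Classification quality is summarized by a 3x3 confusion matrix over
(REM, Wake, NREM) with row-normalized percentages and per-state
recall/precision/F1. Deprivation efficacy compares per-animal state
occupancies between a baseline session and an RSD (REM sleep deprivation)
session: fold changes are baseline/RSD ratios per animal for every state
(so selective REM suppression shows a large REM ratio with Wake and NREM
near 1), summarized by geometric means with bias-corrected percentile
bootstrap 95 % confidence intervals, and tested with an exact paired
Wilcoxon signed-rank test (Pratt handling of zero differences).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .states import STATE_INDEX, STATE_ORDER, Hypnogram, VigilanceState


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts and row percentages; rows = true state, cols = predicted.

    State order is (REM, Wake, NREM) on both axes.
    """

    counts: np.ndarray
    row_pct: np.ndarray

    def to_frame(self, percentages: bool = True) -> pd.DataFrame:
        names = [s.name for s in STATE_ORDER]
        data = self.row_pct if percentages else self.counts
        return pd.DataFrame(data, index=names, columns=names)


def confusion_matrix(truth: Hypnogram, predicted: Hypnogram) -> ConfusionMatrix:
    """Pairwise epoch counts between two aligned hypnograms."""
    if len(truth) != len(predicted):
        raise ValueError(f"length mismatch: truth {len(truth)} vs predicted {len(predicted)}")
    if not np.isclose(truth.epoch_duration, predicted.epoch_duration):
        raise ValueError("epoch durations differ between truth and prediction")
    counts = np.zeros((3, 3), dtype=np.int64)
    t_idx = np.searchsorted([1, 2, 3], truth.labels)
    p_idx = np.searchsorted([1, 2, 3], predicted.labels)
    np.add.at(counts, (t_idx, p_idx), 1)
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        row_pct = np.where(row_sums > 0, 100.0 * counts / row_sums, np.nan)
    return ConfusionMatrix(counts=counts, row_pct=row_pct)


def recall_f1(matrix: ConfusionMatrix) -> dict[VigilanceState, dict[str, float]]:
    """Per-state recall, precision and F1; empty denominators flag NaN."""
    counts = matrix.counts
    out: dict[VigilanceState, dict[str, float]] = {}
    for st in STATE_ORDER:
        i = STATE_INDEX[st]
        tp = counts[i, i]
        row = counts[i].sum()
        col = counts[:, i].sum()
        recall = tp / row if row > 0 else float("nan")
        precision = tp / col if col > 0 else float("nan")
        if np.isnan(recall) or np.isnan(precision) or (recall + precision) == 0:
            f1 = float("nan") if (np.isnan(recall) or np.isnan(precision)) else 0.0
        else:
            f1 = 2 * recall * precision / (recall + precision)
        out[st] = {"recall": float(recall), "precision": float(precision), "f1": float(f1)}
    return out


def occupancy(hypnogram: Hypnogram) -> dict[VigilanceState, float]:
    """Percentage of total time per state; the three values sum to 100."""
    if len(hypnogram) == 0:
        raise ValueError("empty hypnogram")
    out = {}
    for st in STATE_ORDER:
        out[st] = float(100.0 * np.mean(hypnogram.labels == int(st)))
    return out


@dataclass(frozen=True)
class FoldChange:
    """Per-animal baseline/RSD ratios with a geometric-mean summary."""

    ratios: np.ndarray
    geometric_mean: float
    ci95: tuple[float, float]
    zero_adjusted: tuple[int, ...] = ()


def fold_change(
    baseline_occ: Sequence[float],
    rsd_occ: Sequence[float],
    zero_offset: float | None = None,
    n_boot: int = 10_000,
    seed: int = 0,
) -> FoldChange:
    """Baseline-to-RSD occupancy ratios, geometric mean and bootstrap CI.

    ``ratio_i = baseline_i / rsd_i``; the geometric mean is
    ``exp(mean(log ratio))``. When an occupancy is zero, ``zero_offset``
    (typically half of one epoch's worth of occupancy) is added to both
    members of that pair, and the adjusted indices are reported. The 95 % CI
    is a bias-corrected percentile bootstrap over the log ratios, seeded.
    """
    b = np.asarray(baseline_occ, dtype=float)
    r = np.asarray(rsd_occ, dtype=float)
    if b.shape != r.shape or b.ndim != 1 or b.size == 0:
        raise ValueError("baseline and RSD must be equal-length paired per-animal vectors")
    if np.any(b < 0) or np.any(r < 0):
        raise ValueError("occupancies must be non-negative")
    zero_mask = (b == 0) | (r == 0)
    adjusted: tuple[int, ...] = ()
    if np.any(zero_mask):
        if zero_offset is None:
            raise ValueError(
                "zero occupancy present: pass zero_offset (half of one epoch's occupancy)"
            )
        adjusted = tuple(int(i) for i in np.flatnonzero(zero_mask))
        b = b.copy()
        r = r.copy()
        b[zero_mask] += zero_offset
        r[zero_mask] += zero_offset
    log_ratios = np.log(b / r)
    gm = float(np.exp(np.mean(log_ratios)))

    n = log_ratios.size
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    boot = np.exp(np.mean(log_ratios[idx], axis=1))
    if np.allclose(boot, boot[0]):
        ci = (gm, gm)
    else:
        # Bias-corrected percentile bootstrap.
        prop = np.mean(boot < gm)
        prop = min(max(prop, 1.0 / n_boot), 1.0 - 1.0 / n_boot)
        z0 = sstats.norm.ppf(prop)
        z = sstats.norm.ppf([0.025, 0.975])
        alphas = sstats.norm.cdf(2 * z0 + z)
        lo, hi = np.quantile(boot, alphas)
        ci = (float(lo), float(hi))
    return FoldChange(
        ratios=b / r, geometric_mean=gm, ci95=ci, zero_adjusted=adjusted
    )


def _signed_rank_distribution(double_ranks: np.ndarray) -> np.ndarray:
    """Counts of sign assignments per achievable W+ (in doubled-rank units)."""
    total = int(double_ranks.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for dr in double_ranks:
        dr = int(dr)
        new = counts.copy()
        new[dr:] += counts[: total + 1 - dr]
        counts = new
    return counts


def wilcoxon_paired(
    baseline: Sequence[float], rsd: Sequence[float]
) -> dict[str, float]:
    """Exact paired Wilcoxon signed-rank test (two-sided, Pratt zeros).

    Differences are ranked by absolute value with midranks for ties, zeros
    included in the ranking (Pratt) but excluded from the statistic and the
    sign enumeration. The null distribution of W+ (sum of positive ranks)
    is computed exactly, conditional on the observed ranks, by dynamic
    programming over all 2^m sign assignments.
    """
    x = np.asarray(baseline, dtype=float)
    y = np.asarray(rsd, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size == 0:
        raise ValueError("inputs must be equal-length paired vectors")
    d = x - y
    if np.all(d == 0):
        raise ValueError("all paired differences are zero: test degenerate")
    ranks = sstats.rankdata(np.abs(d))  # zeros included (Pratt)
    nonzero = d != 0
    r_nz = ranks[nonzero]
    signs = np.sign(d[nonzero])
    # Doubled ranks are integers even with .5 midranks.
    dr = np.round(2 * r_nz).astype(int)
    w_plus2 = int(np.sum(dr[signs > 0]))
    dist = _signed_rank_distribution(dr)
    total_assignments = dist.sum()
    p_le = dist[: w_plus2 + 1].sum() / total_assignments
    p_ge = dist[w_plus2:].sum() / total_assignments
    p = min(1.0, 2.0 * min(p_le, p_ge))
    return {
        "statistic": float(np.sum(r_nz[signs > 0])),
        "p_two_sided": float(p),
        "n_nonzero": int(nonzero.sum()),
    }


def state_space_export(
    r_theta_delta: Sequence[float],
    emg_rms: Sequence[float],
    labels: Hypnogram,
) -> pd.DataFrame:
    """Long-format (epoch, theta/delta ratio, EMG RMS, state) table.

    The per-epoch joint distribution of the EEG theta/delta ratio and EMG
    amplitude, color-codable by state — REM concentrates at high theta/delta
    and low EMG. No statistics are computed here.
    """
    r = np.asarray(r_theta_delta, dtype=float)
    e = np.asarray(emg_rms, dtype=float)
    if not (len(r) == len(e) == len(labels)):
        raise ValueError(
            f"misaligned inputs: {len(r)} features, {len(e)} EMG values, {len(labels)} labels"
        )
    return pd.DataFrame(
        {
            "epoch": np.arange(len(labels), dtype=int),
            "r_theta_delta": r,
            "emg_rms": e,
            "state": [VigilanceState(int(c)).name for c in labels.labels],
        }
    )


def emg_epoch_rms(samples: np.ndarray, fs: float, epoch_duration: float = 2.5) -> np.ndarray:
    """Per-epoch RMS amplitude of an EMG trace."""
    n_epoch = int(round(fs * epoch_duration))
    n = len(samples) // n_epoch
    x = np.asarray(samples[: n * n_epoch], dtype=float).reshape(n, n_epoch)
    return np.sqrt(np.mean(x**2, axis=1))
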