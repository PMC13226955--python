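"""Threshold rule classification and epoch-level aggregation.

The per-window decision rule partitions the feature plane:

    Wake  if r_hf >= tau_hf                      (regardless of theta/delta)
    REM   if r_theta_delta >= tau_theta_delta and r_hf < tau_hf
    NREM  otherwise

The Wake branch takes precedence over the theta/delta test — the only
reading under which the three branches are total and mutually exclusive.
Undefined (degenerate-spectrum) features classify as Wake with a flag set:
fail-safe, since no actuation decision should ride on garbage.

Decisions arrive at 10 Hz; for offline comparison with 2.5 s scored epochs
each block of 25 consecutive decisions is reduced by majority vote, with
ties broken in the priority order REM > NREM > Wake (missing a REM epoch is
the costly error for a deprivation device).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .calibration import Thresholds
from .spectral import SpectralFeatures
from .states import Hypnogram, VigilanceState

#: Decisions per 2.5 s epoch at the 100 ms control interval.
DECISIONS_PER_EPOCH = 25

#: Tie-break priority for the majority vote (first wins).
TIE_PRIORITY = (VigilanceState.REM, VigilanceState.NREM, VigilanceState.WAKE)


@dataclass(frozen=True)
class Decision:
    """One per-cycle classification, flagged when degraded.

    ``flag`` is '' for a normal decision, 'undefined' when the features were
    degenerate, and 'warmup' while the 5 s window is still filling — both
    degraded cases are forced to Wake.
    """

    state: VigilanceState
    end_time: float
    features: SpectralFeatures | None = None
    flag: str = ""


def classify(features: SpectralFeatures, thresholds: Thresholds) -> Decision:
    """Apply the calibrated threshold rule to one feature pair."""
    if features.undefined or not (
        np.isfinite(features.r_theta_delta) and np.isfinite(features.r_hf)
    ):
        return Decision(
            state=VigilanceState.WAKE,
            end_time=features.end_time,
            features=features,
            flag="undefined",
        )
    if features.r_hf >= thresholds.tau_hf:
        state = VigilanceState.WAKE
    elif features.r_theta_delta >= thresholds.tau_theta_delta:
        state = VigilanceState.REM
    else:
        state = VigilanceState.NREM
    return Decision(state=state, end_time=features.end_time, features=features)


def majority_vote(decisions: Sequence[Decision | VigilanceState]) -> VigilanceState:
    """Modal state over exactly 25 decisions; deterministic tie-break."""
    if len(decisions) != DECISIONS_PER_EPOCH:
        raise ValueError(
            f"majority vote needs exactly {DECISIONS_PER_EPOCH} decisions, got {len(decisions)}"
        )
    states = [d.state if isinstance(d, Decision) else VigilanceState(d) for d in decisions]
    counts = {st: 0 for st in TIE_PRIORITY}
    for s in states:
        counts[s] += 1
    best = max(counts.values())
    for st in TIE_PRIORITY:
        if counts[st] == best:
            return st
    raise AssertionError("unreachable")


def epochize(
    decisions: Sequence[Decision | VigilanceState],
    epoch_duration: float = 2.5,
    step_s: float = 0.1,
    start_time: float = 0.0,
) -> Hypnogram:
    """Aggregate a 10 Hz decision stream into a 2.5 s epoch hypnogram.

    A trailing partial epoch is dropped; output epochs are aligned to the
    session start.
    """
    per_epoch = int(round(epoch_duration / step_s))
    n_epochs = len(decisions) // per_epoch
    labels = np.empty(n_epochs, dtype=np.int8)
    for i in range(n_epochs):
        labels[i] = int(majority_vote(decisions[i * per_epoch:(i + 1) * per_epoch]))
    return Hypnogram(labels=labels, epoch_duration=epoch_duration, start_time=start_time)
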