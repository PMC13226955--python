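"""Per-animal threshold calibration from a labeled baseline recording.

EEG amplitude and electrode impedance vary across animals, so the decision
boundaries are estimated per subject from a baseline session scored into
REM/Wake/NREM epochs:

    tau_theta_delta = mean(R_theta_delta | REM)  - sd(R_theta_delta | REM)
    tau_hf          = mean(R_hf | NREM)          + sd(R_hf | NREM)

The REM threshold sits one SD below the REM centre so that most genuine REM
windows exceed it; the high-frequency threshold sits one SD above the NREM
centre so that quiet sleep stays below it while wake and movement artifacts
cross it. SDs are sample standard deviations (n-1 denominator).

A validation gate compares classifier recall per state on a held-out
session against configured minima before closed-loop mode is allowed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .spectral import SpectralFeatures
from .states import STATE_ORDER, Hypnogram, VigilanceState


class CalibrationError(ValueError):
    """Raised when baseline data cannot support threshold estimation."""


@dataclass(frozen=True)
class StateStats:
    n_epochs: int
    mean_r_theta_delta: float
    sd_r_theta_delta: float
    mean_r_hf: float
    sd_r_hf: float


@dataclass(frozen=True)
class StateFeatureStats:
    """Per-state feature summaries over labeled baseline epochs."""

    per_state: dict[VigilanceState, StateStats]

    def require(self, state: VigilanceState) -> StateStats:
        if state not in self.per_state:
            raise CalibrationError(
                f"no epochs of state {state.name} in baseline; cannot calibrate"
            )
        return self.per_state[state]


@dataclass(frozen=True)
class Thresholds:
    """Calibrated per-animal decision boundaries."""

    tau_theta_delta: float
    tau_hf: float
    animal_id: str = ""
    source_stats: StateFeatureStats | None = None

    def to_dict(self) -> dict:
        d: dict = {
            "animal_id": self.animal_id,
            "tau_theta_delta": self.tau_theta_delta,
            "tau_hf": self.tau_hf,
        }
        if self.source_stats is not None:
            d["stats"] = {
                st.name: vars(s) for st, s in self.source_stats.per_state.items()
            }
        return d

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "Thresholds":
        d = json.loads(Path(path).read_text())
        stats = None
        if "stats" in d:
            stats = StateFeatureStats(
                per_state={
                    VigilanceState[name]: StateStats(**s) for name, s in d["stats"].items()
                }
            )
        return cls(
            tau_theta_delta=float(d["tau_theta_delta"]),
            tau_hf=float(d["tau_hf"]),
            animal_id=str(d.get("animal_id", "")),
            source_stats=stats,
        )


def state_feature_stats(
    features: Sequence[SpectralFeatures],
    labels: Hypnogram,
    exclude: Sequence[bool] | None = None,
) -> StateFeatureStats:
    """Per-state mean/SD of the two features over labeled epochs.

    ``features`` and ``labels`` must be aligned 1:1 on epochs. Epochs with
    ``exclude`` set (e.g. during active platform motion) or with undefined
    features are left out. States with fewer than two usable epochs are
    omitted from the result; downstream threshold estimation fails loudly if
    a required state is missing.
    """
    if len(features) != len(labels):
        raise ValueError(
            f"features ({len(features)}) and labels ({len(labels)}) must align per epoch"
        )
    if exclude is not None and len(exclude) != len(labels):
        raise ValueError("exclude mask must align with epochs")
    per_state: dict[VigilanceState, StateStats] = {}
    codes = labels.labels
    r_td = np.array([f.r_theta_delta for f in features])
    r_hf = np.array([f.r_hf for f in features])
    usable = np.array([not f.undefined for f in features])
    if exclude is not None:
        usable &= ~np.asarray(exclude, dtype=bool)
    for st in STATE_ORDER:
        m = usable & (codes == int(st))
        n = int(np.sum(m))
        if n < 2:
            continue
        per_state[st] = StateStats(
            n_epochs=n,
            mean_r_theta_delta=float(np.mean(r_td[m])),
            sd_r_theta_delta=float(np.std(r_td[m], ddof=1)),
            mean_r_hf=float(np.mean(r_hf[m])),
            sd_r_hf=float(np.std(r_hf[m], ddof=1)),
        )
    if not per_state:
        raise CalibrationError("no state has >= 2 usable epochs")
    return StateFeatureStats(per_state=per_state)


def estimate_thresholds(stats: StateFeatureStats, animal_id: str = "") -> Thresholds:
    """Thresholds from baseline statistics: REM mean−SD and NREM mean+SD."""
    rem = stats.require(VigilanceState.REM)
    nrem = stats.require(VigilanceState.NREM)
    tau_td = rem.mean_r_theta_delta - rem.sd_r_theta_delta
    tau_hf = nrem.mean_r_hf + nrem.sd_r_hf
    if not (np.isfinite(tau_td) and np.isfinite(tau_hf)):
        raise CalibrationError("non-finite threshold from baseline statistics")
    return Thresholds(
        tau_theta_delta=float(tau_td),
        tau_hf=float(tau_hf),
        animal_id=animal_id,
        source_stats=stats,
    )


DEFAULT_RECALL_GATE: Mapping[VigilanceState, float] = {
    VigilanceState.REM: 0.8,
    VigilanceState.WAKE: 0.7,
    VigilanceState.NREM: 0.8,
}


@dataclass(frozen=True)
class ValidationGate:
    """Outcome of the pre-closed-loop validation check."""

    recalls: dict[VigilanceState, float]
    gate: dict[VigilanceState, float]
    passed: bool
    details: dict[VigilanceState, str] = field(default_factory=dict)


def validate_thresholds(
    features: Sequence[SpectralFeatures],
    labels: Hypnogram,
    thresholds: Thresholds,
    acceptance: Mapping[VigilanceState, float] = DEFAULT_RECALL_GATE,
) -> ValidationGate:
    """Gate closed-loop entry on per-state recall over a held-out session.

    A state absent from the validation session fails the gate explicitly —
    the check never passes silently on missing data.
    """
    from .classify import classify  # local import to avoid a cycle

    if len(labels) == 0:
        raise ValueError("empty validation session")
    if len(features) != len(labels):
        raise ValueError("features and labels must align per epoch")
    predicted = np.array([int(classify(f, thresholds).state) for f in features])
    codes = labels.labels
    recalls: dict[VigilanceState, float] = {}
    details: dict[VigilanceState, str] = {}
    passed = True
    for st, minimum in acceptance.items():
        m = codes == int(st)
        n = int(np.sum(m))
        if n == 0:
            recalls[st] = float("nan")
            details[st] = "state absent from validation session"
            passed = False
            continue
        rec = float(np.mean(predicted[m] == int(st)))
        recalls[st] = rec
        if rec < minimum:
            details[st] = f"recall {rec:.3f} below gate {minimum:.3f}"
            passed = False
    return ValidationGate(recalls=recalls, gate=dict(acceptance), passed=passed, details=details)
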