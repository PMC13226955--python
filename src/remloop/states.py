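"""Vigilance states and hypnograms.

Three-state sleep scoring (REM, Wake, NREM) at a fixed epoch duration.
Integer codes follow the AccuSleep convention: 1 = REM, 2 = Wake, 3 = NREM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class VigilanceState(IntEnum):
    """Vigilance state with the AccuSleep integer codes."""

    REM = 1
    WAKE = 2
    NREM = 3


#: Fixed state ordering used for matrices and reports: rows/cols are (REM, Wake, NREM).
STATE_ORDER: tuple[VigilanceState, ...] = (
    VigilanceState.REM,
    VigilanceState.WAKE,
    VigilanceState.NREM,
)

#: Index of each state within STATE_ORDER.
STATE_INDEX: dict[VigilanceState, int] = {s: i for i, s in enumerate(STATE_ORDER)}


@dataclass(frozen=True)
class Hypnogram:
    """A sequence of vigilance-state labels at fixed epoch resolution.

    Parameters
    ----------
    labels
        Integer state codes, one per epoch (1 = REM, 2 = Wake, 3 = NREM).
    epoch_duration
        Epoch length in seconds (> 0). The scoring convention here is 2.5 s.
    start_time
        Session-relative start of the first epoch, in seconds.
    """

    labels: np.ndarray
    epoch_duration: float = 2.5
    start_time: float = 0.0

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=np.int8)
        valid = {int(s) for s in VigilanceState}
        if labels.ndim != 1:
            raise ValueError("hypnogram labels must be one-dimensional")
        if labels.size and not set(np.unique(labels)).issubset(valid):
            bad = sorted(set(np.unique(labels)) - valid)
            raise ValueError(f"invalid state codes in hypnogram: {bad}")
        if self.epoch_duration <= 0:
            raise ValueError("epoch_duration must be positive")
        object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return int(self.labels.size)

    @property
    def duration(self) -> float:
        """Total covered time in seconds."""
        return len(self) * self.epoch_duration

    def states(self) -> list[VigilanceState]:
        return [VigilanceState(int(c)) for c in self.labels]

    def epoch_starts(self) -> np.ndarray:
        return self.start_time + np.arange(len(self)) * self.epoch_duration

    @classmethod
    def from_states(
        cls,
        states: Iterable[VigilanceState | int],
        epoch_duration: float = 2.5,
        start_time: float = 0.0,
    ) -> "Hypnogram":
        return cls(
            labels=np.asarray([int(s) for s in states], dtype=np.int8),
            epoch_duration=epoch_duration,
            start_time=start_time,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch_index": np.arange(len(self), dtype=int),
                "start_s": self.epoch_starts(),
                "state_code": self.labels.astype(int),
            }
        )

    def to_csv(self, path: str | Path) -> None:
        """Write `epoch_index,start_s,state_code` CSV."""
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path, epoch_duration: float | None = None) -> "Hypnogram":
        """Read a hypnogram CSV written by :meth:`to_csv`.

        The epoch duration is inferred from consecutive ``start_s`` values
        unless given explicitly (required for single-epoch files).
        """
        df = pd.read_csv(path)
        required = {"epoch_index", "start_s", "state_code"}
        if not required.issubset(df.columns):
            raise ValueError(f"hypnogram CSV missing columns {required - set(df.columns)}")
        if epoch_duration is None:
            if len(df) < 2:
                raise ValueError("cannot infer epoch_duration from fewer than 2 epochs")
            steps = np.diff(df["start_s"].to_numpy())
            if not np.allclose(steps, steps[0]):
                raise ValueError("non-uniform epoch starts in hypnogram CSV")
            epoch_duration = float(steps[0])
        start = float(df["start_s"].iloc[0]) if len(df) else 0.0
        return cls(
            labels=df["state_code"].to_numpy(dtype=np.int8),
            epoch_duration=float(epoch_duration),
            start_time=start,
        )


@dataclass(frozen=True)
class SignalTrace:
    """A single-channel continuous recording in millivolts.

    ``fs`` defaults to the acquisition rate of 1 kHz; samples are expected to
    lie within the ±5 mV ADC range (the synthesizer clips and counts
    out-of-range samples).
    """

    samples: np.ndarray
    fs: float = 1000.0
    channel: str = "EEG"
    start_time: float = 0.0
    n_clipped: int = 0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError("trace samples must be one-dimensional")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.channel not in ("EEG", "EMG"):
            raise ValueError("channel must be 'EEG' or 'EMG'")
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        return len(self) / self.fs
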