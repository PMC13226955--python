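"""Run configuration with validated acquisition and control constants.

Defaults encode the reference operating point: 1 kHz sampling, a 5 s
analysis window stepped every 100 ms (10 Hz update, 98 % overlap), a
10,000-point FFT (0.1 Hz bins), 2.5 s scoring epochs (25 decisions per
epoch), and the delta/theta/high-frequency/total bands. Every invariant
tying these together is checked when a config is loaded, so a bad file
fails with a named error instead of a misconfigured run.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    sampling_rate: float = 1000.0
    window_s: float = 5.0
    step_ms: float = 100.0
    n_fft: int = 10_000
    epoch_s: float = 2.5
    bands: dict = field(
        default_factory=lambda: {
            "delta": [0.5, 4.0],
            "theta": [4.0, 8.0],
            "hf": [90.0, 200.0],
            "total": [0.5, 500.0],
        }
    )
    animal_model_path: str | None = None
    seed: int = 0
    duration_s: float = 86_400.0
    max_rem_seconds: float | None = None
    recall_gate: dict = field(
        default_factory=lambda: {"REM": 0.8, "WAKE": 0.7, "NREM": 0.8}
    )
    actuator: dict = field(default_factory=dict)

    @property
    def window_samples(self) -> int:
        return int(round(self.window_s * self.sampling_rate))

    @property
    def decisions_per_epoch(self) -> int:
        return int(round(self.epoch_s / (self.step_ms / 1000.0)))

    @property
    def update_rate_hz(self) -> float:
        return 1000.0 / self.step_ms

    def validate(self) -> "RunConfig":
        if self.sampling_rate <= 0:
            raise ConfigError("sampling_rate must be positive")
        if abs(self.window_s * self.sampling_rate - round(self.window_s * self.sampling_rate)) > 1e-9:
            raise ConfigError("window_s x sampling_rate must be an integer sample count")
        if self.n_fft < self.window_samples:
            raise ConfigError(
                f"n_fft ({self.n_fft}) must be >= window samples ({self.window_samples})"
            )
        step_s = self.step_ms / 1000.0
        ratio = self.epoch_s / step_s
        if abs(ratio - round(ratio)) > 1e-9:
            raise ConfigError(
                f"epoch_s / step must be an integer number of decisions per epoch, got {ratio}"
            )
        step_samples = step_s * self.sampling_rate
        if abs(step_samples - round(step_samples)) > 1e-9:
            raise ConfigError("step_ms x sampling_rate must be an integer sample count")
        nyquist = self.sampling_rate / 2
        for name, (lo, hi) in self.bands.items():
            if not (0 <= lo < hi <= nyquist):
                raise ConfigError(f"band '{name}' [{lo}, {hi}] invalid for fs {self.sampling_rate}")
        return self

    def to_dict(self) -> dict:
        return asdict(self)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict())
        )
        path.write_text(text)


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML/JSON config; missing keys take defaults.

    ``None`` or an empty file yields the full default configuration.
    """
    data: dict = {}
    if path is not None:
        raw = Path(path).read_text()
        loaded = yaml.safe_load(raw)
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ConfigError("config file must contain a mapping")
            data = loaded
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data).validate()
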