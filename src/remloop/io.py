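"""Signal and table I/O.

Native signal format: raw float32 little-endian binary (samples x channels,
C order) plus a JSON sidecar describing sampling rate, channel names, units
and sample count. The sidecar makes truncation detectable: a size mismatch
raises instead of silently reading a partial file. EDF files are read via
:mod:`mne` when available (read-only; the native format is the write path).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .states import SignalTrace

_SIDECAR_SUFFIX = ".json"
_DATA_SUFFIX = ".dat"


class SignalIOError(IOError):
    pass


def write_signals(traces: list[SignalTrace], stem: str | Path) -> tuple[Path, Path]:
    """Write channels as interleaved float32-LE binary + JSON sidecar.

    ``stem`` is the path without suffix; ``<stem>.dat`` and ``<stem>.json``
    are produced. All traces must share fs, length and start time.
    """
    if not traces:
        raise ValueError("no traces to write")
    fs = traces[0].fs
    n = len(traces[0])
    if any(t.fs != fs or len(t) != n for t in traces):
        raise ValueError("all traces must share sampling rate and length")
    stem = Path(stem)
    data_path = stem.with_suffix(_DATA_SUFFIX)
    sidecar_path = stem.with_suffix(_SIDECAR_SUFFIX)
    data = np.stack([t.samples for t in traces], axis=1).astype("<f4")
    data.tofile(data_path)
    sidecar = {
        "fs": fs,
        "channels": [t.channel for t in traces],
        "n_samples": n,
        "start_time": traces[0].start_time,
        "units": "mV",
        "dtype": "float32-le",
        "order": "samples x channels, C order",
    }
    sidecar_path.write_text(json.dumps(sidecar, indent=2))
    return data_path, sidecar_path


def read_signals(path: str | Path) -> list[SignalTrace]:
    """Read signals written by :func:`write_signals`, or an EDF file.

    ``path`` may be the ``.dat`` file, the ``.json`` sidecar, the bare stem,
    or an ``.edf`` recording.
    """
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return _read_edf(path)
    stem = path.with_suffix("")
    data_path = stem.with_suffix(_DATA_SUFFIX)
    sidecar_path = stem.with_suffix(_SIDECAR_SUFFIX)
    if not sidecar_path.exists():
        raise SignalIOError(f"missing sidecar {sidecar_path}")
    if not data_path.exists():
        raise SignalIOError(f"missing data file {data_path}")
    meta = json.loads(sidecar_path.read_text())
    for key in ("fs", "channels", "n_samples"):
        if key not in meta:
            raise SignalIOError(f"sidecar missing field '{key}'")
    n, channels = int(meta["n_samples"]), list(meta["channels"])
    expected_bytes = n * len(channels) * 4
    actual = data_path.stat().st_size
    if actual != expected_bytes:
        raise SignalIOError(
            f"corrupt signal file: expected {expected_bytes} bytes "
            f"({n} samples x {len(channels)} channels), found {actual}"
        )
    data = np.fromfile(data_path, dtype="<f4").reshape(n, len(channels))
    start = float(meta.get("start_time", 0.0))
    return [
        SignalTrace(
            samples=data[:, i].astype(np.float64),
            fs=float(meta["fs"]),
            channel=ch,
            start_time=start,
        )
        for i, ch in enumerate(channels)
    ]


def _read_edf(path: Path) -> list[SignalTrace]:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise SignalIOError("reading EDF requires the optional 'mne' package") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    out = []
    for i, name in enumerate(raw.ch_names):
        channel = "EMG" if "emg" in name.lower() else "EEG"
        # mne returns volts; the pipeline works in mV.
        out.append(
            SignalTrace(samples=raw.get_data(picks=[i])[0] * 1e3, fs=fs, channel=channel)
        )
    return out
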