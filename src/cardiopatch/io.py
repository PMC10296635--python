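"""Reading and writing recordings and derived results.

WAV is the canonical interchange format (the device streams audio over a
USB audio codec); the ECG rides along as an extra WAV channel or as a
``time,value`` CSV. PCM samples are scaled to [-1, 1] floats on read.
Mismatched or non-uniform sampling is refused rather than silently
resampled.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .core import TimeSeries

__all__ = ["read_recording", "read_wav", "read_csv_signal", "write_wav", "config_hash"]

_PCM_SCALE = {
    np.dtype(np.int16): 2.0**15,
    np.dtype(np.int32): 2.0**31,
}


def read_wav(path: str | Path) -> tuple[float, np.ndarray]:
    """Read a WAV file as float samples in [-1, 1], shape (n, channels)."""
    fs, data = wavfile.read(str(path))
    if data.dtype in _PCM_SCALE:
        data = data.astype(float) / _PCM_SCALE[data.dtype]
    elif data.dtype == np.uint8:  # 8-bit WAV is unsigned
        data = (data.astype(float) - 128.0) / 128.0
    else:
        data = data.astype(float)
    if data.ndim == 1:
        data = data[:, None]
    return float(fs), data


def read_csv_signal(path: str | Path, rel_jitter: float = 1e-6) -> TimeSeries:
    """Read a ``time,value`` CSV as a uniformly sampled series.

    The timestamps must be uniform within ``rel_jitter`` relative
    deviation of the median step; anything else raises.
    """
    df = pd.read_csv(path)
    cols = {c.strip().lower(): c for c in df.columns}
    if "time" not in cols or "value" not in cols:
        raise ValueError(f"CSV {path} must have 'time' and 'value' columns")
    t = df[cols["time"]].to_numpy(dtype=float)
    v = df[cols["value"]].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError("CSV signal needs at least 2 samples")
    dt = np.diff(t)
    med = float(np.median(dt))
    if med <= 0 or np.max(np.abs(dt - med)) > rel_jitter * med:
        raise ValueError(f"non-uniform sampling in {path}")
    return TimeSeries(v, fs=1.0 / med, t0=float(t[0]))


def read_recording(
    path: str | Path, channel_map: dict[str, int] | None = None
) -> dict[str, TimeSeries]:
    """Read a multi-channel WAV or a single-channel CSV into named series.

    ``channel_map`` names WAV channels by index, e.g.
    ``{"ecg": 0, "primary": 1, "reference": 2}``. A CSV always yields one
    channel, named by the single key of ``channel_map`` (default
    ``"signal"``).
    """
    path = Path(path)
    if path.suffix.lower() == ".wav":
        fs, data = read_wav(path)
        if channel_map is None:
            channel_map = {f"ch{i}": i for i in range(data.shape[1])}
        out = {}
        for name, idx in channel_map.items():
            if not 0 <= idx < data.shape[1]:
                raise ValueError(
                    f"channel {name!r} maps to index {idx} but {path.name} has "
                    f"{data.shape[1]} channel(s)"
                )
            out[name] = TimeSeries(data[:, idx], fs=fs)
        return out
    if path.suffix.lower() == ".csv":
        name = "signal"
        if channel_map:
            if len(channel_map) != 1:
                raise ValueError("CSV carries a single channel")
            name = next(iter(channel_map))
        return {name: read_csv_signal(path)}
    raise ValueError(f"unknown extension {path.suffix!r} (expected .wav or .csv)")


def write_wav(
    path: str | Path, channels: list[TimeSeries] | TimeSeries, subtype: str = "float32"
) -> None:
    """Write one or more equal-rate series as a WAV file.

    ``subtype``: ``float32`` (lossless for analysis outputs) or ``pcm16``
    (interchange with audio tools; clips outside [-1, 1]).
    """
    if isinstance(channels, TimeSeries):
        channels = [channels]
    fs = channels[0].fs
    if any(c.fs != fs for c in channels) or any(len(c) != len(channels[0]) for c in channels):
        raise ValueError("all channels must share fs and length")
    data = np.column_stack([c.samples for c in channels])
    if data.shape[1] == 1:
        data = data[:, 0]
    if subtype == "float32":
        wavfile.write(str(path), int(round(fs)), data.astype(np.float32))
    elif subtype == "pcm16":
        clipped = np.clip(data, -1.0, 1.0 - 2.0**-15)
        wavfile.write(str(path), int(round(fs)), np.round(clipped * 2.0**15).astype(np.int16))
    else:
        raise ValueError(f"unknown subtype {subtype!r}")


def config_hash(config: dict) -> str:
    """Stable short hash of a resolved configuration (reproducibility tag)."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
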