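"""Core signal containers shared by every stage of the processing chain.

The patch produces uniformly sampled, time-synchronized channels (ECG,
primary stethoscope microphone, ambient reference microphone).
:class:`TimeSeries` is the universal carrier for one such channel;
:class:`StereoRecording` pairs the two microphones for adaptive noise
cancellation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TimeSeries", "StereoRecording"]


@dataclass
class TimeSeries:
    """A uniformly sampled real-valued signal.

    Parameters
    ----------
    samples
        Sample amplitudes. Units depend on the signal: mV for ECG,
        arbitrary acoustic units for microphone channels.
    fs
        Sampling rate in Hz. Must be positive.
    t0
        Time of the first sample in seconds (default 0).
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.samples.size < 1:
            raise ValueError("TimeSeries needs at least one sample")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Record length in seconds (number of samples / fs)."""
        return self.samples.size / self.fs

    def times(self) -> np.ndarray:
        """Sample times in seconds, ``t0 + n/fs``."""
        return self.t0 + np.arange(self.samples.size) / self.fs

    def copy_with(self, samples: np.ndarray) -> "TimeSeries":
        """New series with the same time base but different samples."""
        return TimeSeries(np.asarray(samples, dtype=float), self.fs, self.t0)


@dataclass
class StereoRecording:
    """Paired microphone channels for adaptive noise cancellation.

    ``primary`` is the stethoscope microphone (wanted sounds plus
    channel-filtered ambient noise); ``reference`` is the ambient
    microphone observing noise only. Both channels must share length
    and sampling rate.
    """

    primary: TimeSeries
    reference: TimeSeries

    def __post_init__(self) -> None:
        if len(self.primary) != len(self.reference):
            raise ValueError("primary and reference must have equal length")
        if self.primary.fs != self.reference.fs:
            raise ValueError("primary and reference must share sampling rate")

    @property
    def fs(self) -> float:
        return self.primary.fs

    def __len__(self) -> int:
        return len(self.primary)
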