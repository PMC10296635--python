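"""STFT spectrogram of heart (and lung) sound.

The display software computes the heart-sound spectrogram by short-time
Fourier transform at 4000 samples/s with an FFT size of 2048 samples,
i.e. a frame every 2048/4000 = 512 ms and a frequency resolution of
4000/2048 ~ 1.95 Hz. Frames are non-overlapping by default (hop = FFT
size); overlap and window are exposed as options.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core import TimeSeries

__all__ = ["Spectrogram", "stft_spectrogram", "frequency_resolution"]


@dataclass
class Spectrogram:
    """One-sided magnitude spectrogram.

    ``magnitude`` is frames x bins, non-negative; ``times`` are frame
    centers in s; ``freqs`` bin centers in Hz, spaced fs/fft_size.
    """

    times: np.ndarray
    freqs: np.ndarray
    magnitude: np.ndarray
    fft_size: int
    hop: int
    window_name: str
    fs: float

    def to_db(self, floor_db: float = -120.0) -> np.ndarray:
        """Magnitude in dB relative to the maximum, floored for display."""
        ref = self.magnitude.max()
        if ref == 0:
            return np.full_like(self.magnitude, floor_db)
        with np.errstate(divide="ignore"):
            db = 20.0 * np.log10(self.magnitude / ref)
        return np.maximum(db, floor_db)


def stft_spectrogram(
    ts: TimeSeries,
    fft_size: int = 2048,
    hop: int | None = None,
    window: str = "hann",
) -> Spectrogram:
    """Short-time Fourier transform magnitude spectrogram.

    Frames of ``fft_size`` samples are taken every ``hop`` samples
    (default: hop = fft_size, non-overlapping), windowed, and transformed
    with a one-sided FFT; a trailing partial frame is dropped. Magnitudes
    are stored linearly; dB conversion is a display concern
    (:meth:`Spectrogram.to_db`).
    """
    if fft_size < 2:
        raise ValueError("fft_size must be >= 2")
    hop = fft_size if hop is None else int(hop)
    if hop < 1:
        raise ValueError("hop must be >= 1")
    n = len(ts)
    if n < fft_size:
        raise ValueError(f"signal shorter than one frame ({n} < {fft_size})")
    win = sps.get_window(window, fft_size, fftbins=True)
    n_frames = (n - fft_size) // hop + 1
    starts = np.arange(n_frames) * hop
    frames = np.lib.stride_tricks.sliding_window_view(ts.samples, fft_size)[starts]
    mag = np.abs(np.fft.rfft(frames * win, axis=1))
    times = ts.t0 + (starts + fft_size / 2) / ts.fs
    freqs = np.fft.rfftfreq(fft_size, d=1.0 / ts.fs)
    return Spectrogram(
        times=times,
        freqs=freqs,
        magnitude=mag,
        fft_size=fft_size,
        hop=hop,
        window_name=window,
        fs=ts.fs,
    )


def frequency_resolution(spec: Spectrogram) -> float:
    """Bin spacing fs / fft_size in Hz."""
    return spec.fs / spec.fft_size
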