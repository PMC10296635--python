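"""Chebyshev band-pass separation of heart and lung sounds.

The stethoscope picks up heart and lung sounds superimposed; they are
separated by band-pass filtering: heart sounds live in 25-100 Hz (dominant
energy near 48 Hz), lung sounds in 300-1800 Hz. Filters are Chebyshev
type I, applied as second-order sections for numerical stability at the
narrow low band relative to the 4 kHz sampling rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core import TimeSeries

__all__ = [
    "FilterSpec",
    "design_bandpass",
    "heart_band",
    "lung_band",
    "apply_filter",
    "HEART_BAND_HZ",
    "LUNG_BAND_HZ",
]

#: Heart-sound pass band (Hz): avoids mixing with lung sounds.
HEART_BAND_HZ = (25.0, 100.0)
#: Lung-sound pass band (Hz): captures normal and abnormal lung sounds.
LUNG_BAND_HZ = (300.0, 1800.0)


@dataclass(frozen=True)
class FilterSpec:
    """A designed Chebyshev type-I band-pass filter.

    ``sos`` holds the second-order-section coefficients; ``band`` the
    passband edges in Hz; ``fs`` the design sampling rate.
    """

    family: str
    order: int
    ripple_db: float
    band: tuple[float, float]
    fs: float
    sos: np.ndarray

    def frequency_response(self, freqs_hz: np.ndarray) -> np.ndarray:
        """Complex response of a single causal pass at the given frequencies."""
        _, h = sps.sosfreqz(self.sos, worN=np.atleast_1d(freqs_hz), fs=self.fs)
        return h


def design_bandpass(
    low_hz: float,
    high_hz: float,
    fs: float,
    order: int = 4,
    ripple_db: float = 0.5,
) -> FilterSpec:
    """Design a stable Chebyshev type-I band-pass filter.

    Parameters
    ----------
    low_hz, high_hz
        Passband edges in Hz; must satisfy ``0 < low < high < fs/2``.
    fs
        Sampling rate in Hz.
    order
        Filter order per edge (default 4).
    ripple_db
        Maximum passband ripple in dB (default 0.5).
    """
    if not 0 < low_hz < high_hz:
        raise ValueError(f"invalid band ({low_hz}, {high_hz}) Hz")
    if high_hz >= fs / 2:
        raise ValueError(
            f"band exceeds Nyquist: high edge {high_hz} Hz >= fs/2 = {fs / 2} Hz"
        )
    if order < 2:
        raise ValueError("order must be >= 2")
    sos = sps.cheby1(
        order, ripple_db, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos"
    )
    _, poles, _ = sps.sos2zpk(sos)
    if not np.all(np.abs(poles) < 1.0):
        raise ValueError("designed filter is unstable (pole outside unit circle)")
    return FilterSpec(
        family="Chebyshev-I",
        order=order,
        ripple_db=ripple_db,
        band=(float(low_hz), float(high_hz)),
        fs=float(fs),
        sos=sos,
    )


def heart_band(fs: float = 4000.0, order: int = 4, ripple_db: float = 0.5) -> FilterSpec:
    """The 25-100 Hz heart-sound band-pass at the given sampling rate."""
    return design_bandpass(*HEART_BAND_HZ, fs=fs, order=order, ripple_db=ripple_db)


def lung_band(fs: float = 4000.0, order: int = 4, ripple_db: float = 0.5) -> FilterSpec:
    """The 300-1800 Hz lung-sound band-pass at the given sampling rate."""
    return design_bandpass(*LUNG_BAND_HZ, fs=fs, order=order, ripple_db=ripple_db)


def apply_filter(
    ts: TimeSeries,
    spec: FilterSpec,
    zero_phase: bool = True,
    zi: np.ndarray | None = None,
) -> TimeSeries | tuple[TimeSeries, np.ndarray]:
    """Apply a designed band-pass to a signal.

    ``zero_phase=True`` (offline analysis default) runs forward-backward
    filtering so event timings are not delayed; ``zero_phase=False`` is a
    single causal pass matching the streaming behaviour of the device.
    Passing ``zi`` (causal mode only) carries filter state across blocks
    and returns ``(filtered, zf)``.
    """
    if ts.fs != spec.fs:
        raise ValueError(f"sampling-rate mismatch: signal {ts.fs} Hz, filter {spec.fs} Hz")
    if zero_phase:
        if zi is not None:
            raise ValueError("block state is only meaningful in causal mode")
        out = sps.sosfiltfilt(spec.sos, ts.samples)
        return ts.copy_with(out)
    if zi is None:
        out = sps.sosfilt(spec.sos, ts.samples)
        return ts.copy_with(out)
    out, zf = sps.sosfilt(spec.sos, ts.samples, zi=zi)
    return ts.copy_with(out), zf


def causal_initial_state(spec: FilterSpec) -> np.ndarray:
    """Zero initial conditions for block-wise causal filtering."""
    return np.zeros((spec.sos.shape[0], 2))
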