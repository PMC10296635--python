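"""Derived cardiopulmonary parameters from ECG and heart/lung sounds.

This is the display layer of the processing chain: from the ECG it
derives R peaks, Q onsets and heart rate; from the heart-sound envelope
the S1/S2 peaks with their intensities, the S1-S2 interval (INTERVAL),
and the electromechanical activation time (EMAT: Q-wave onset on the ECG
to the peak of S1, an index of cardiac contractility); from the
lung-sound envelope the inspiration/expiration phases.

Detection strategy: because the patch inherently records a synchronized
ECG, heart-sound events are gated by ECG landmarks — detect R peaks
first (robust), backtrack each to its Q onset, then pick S1 as the
envelope maximum in a physiologic window after the Q onset and S2 in a
window after S1. All gating windows are configurable. Timing outputs are
invariant to the overall amplitude scale of the inputs; summaries are
medians, for robustness to missed beats.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .core import TimeSeries
from .synth import BeatAnnotations, BreathTruth

__all__ = [
    "SoundAnnotations",
    "CardioParams",
    "SeriesSummary",
    "envelope",
    "detect_r_peaks",
    "detect_q_onset",
    "heart_rate",
    "detect_s1_s2",
    "emat",
    "s1_s2_interval",
    "segment_breaths",
    "compute_cardio_params",
]


@dataclass
class SeriesSummary:
    """A per-beat series with a median summary over the analysis window."""

    times: np.ndarray
    values: np.ndarray
    summary: float

    def __len__(self) -> int:
        return self.values.size


@dataclass
class SoundAnnotations:
    """Per-beat S1/S2 peak times and envelope intensities.

    ``beat_index`` links each record back to the beat annotations it was
    gated by; missing detections are skipped, never fabricated.
    ``s1_low_confidence``/``s2_low_confidence`` flag envelope peaks below
    the noise floor (5x the median envelope).
    """

    beat_index: np.ndarray
    s1_time: np.ndarray
    s2_time: np.ndarray
    s1_intensity: np.ndarray
    s2_intensity: np.ndarray
    s1_low_confidence: np.ndarray
    s2_low_confidence: np.ndarray

    def __post_init__(self) -> None:
        if self.s1_time.size and np.any(self.s2_time <= self.s1_time):
            raise ValueError("S1 must precede S2 in every beat")

    def __len__(self) -> int:
        return self.beat_index.size


@dataclass
class CardioParams:
    """The tablet-panel summary: HR, EMAT, INTERVAL, S1/S2 intensities."""

    hr_bpm: SeriesSummary
    emat_ms: SeriesSummary
    interval_ms: SeriesSummary
    s1_intensity: SeriesSummary
    s2_intensity: SeriesSummary

    def summary_dict(self) -> dict:
        return {
            "hr_bpm": self.hr_bpm.summary,
            "emat_ms": self.emat_ms.summary,
            "interval_ms": self.interval_ms.summary,
            "s1_intensity": self.s1_intensity.summary,
            "s2_intensity": self.s2_intensity.summary,
        }


def _moving_average(x: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return x
    kernel = np.ones(width) / width
    return np.convolve(x, kernel, mode="same")


def envelope(ts: TimeSeries, method: str = "analytic", smooth_ms: float = 20.0) -> TimeSeries:
    """Non-negative envelope outlining the signal's amplitude extremes.

    ``analytic``: magnitude of the analytic (Hilbert) signal, then
    moving-average smoothed over ``smooth_ms``. ``rms``: sliding RMS over
    a ``smooth_ms`` window.
    """
    n = len(ts)
    width = int(round(smooth_ms / 1000.0 * ts.fs))
    if width > n:
        raise ValueError(f"smoothing window ({width} samples) longer than signal ({n})")
    if method == "analytic":
        env = np.abs(sps.hilbert(ts.samples))
        env = _moving_average(env, width)
    elif method == "rms":
        sq = _moving_average(ts.samples**2, max(width, 1))
        env = np.sqrt(sq)
    else:
        raise ValueError(f"unknown envelope method {method!r}")
    return ts.copy_with(env)


def detect_r_peaks(ecg: TimeSeries, refractory_s: float = 0.250) -> np.ndarray:
    """Detect R-peak times with a derivative-energy detector.

    Band-pass 5-30 Hz (QRS energy), square, integrate over a 150 ms
    moving window, pick peaks above an adaptive threshold with a 250 ms
    refractory period, then refine each to the local ECG maximum.
    """
    fs = ecg.fs
    if ecg.duration < 2.0:
        raise ValueError("need at least 2 s of ECG")
    sos = sps.butter(2, [5.0, 30.0], btype="bandpass", fs=fs, output="sos")
    bp = sps.sosfiltfilt(sos, ecg.samples)
    energy = _moving_average(bp**2, int(round(0.150 * fs)))
    peaks, _ = sps.find_peaks(energy, distance=max(1, int(round(refractory_s * fs))))
    if peaks.size == 0:
        warnings.warn("no R peaks found", stacklevel=2)
        return np.array([])
    heights = energy[peaks]
    # adaptive threshold: a fraction of the typical strong-candidate height
    thr = 0.25 * np.median(heights[heights >= np.percentile(heights, 75)])
    peaks = peaks[heights >= thr]
    if peaks.size == 0:
        warnings.warn("no R peaks above threshold", stacklevel=2)
        return np.array([])
    # refine: local maximum of the raw ECG within +-50 ms
    half = int(round(0.050 * fs))
    refined = []
    for p in peaks:
        lo, hi = max(0, p - half), min(len(ecg), p + half + 1)
        refined.append(lo + int(np.argmax(ecg.samples[lo:hi])))
    refined = np.unique(refined)
    return ecg.t0 + refined / fs


def detect_q_onset(
    ecg: TimeSeries,
    r_peaks: np.ndarray,
    search_back_s: float = 0.080,
    slope_fraction: float = 0.05,
) -> BeatAnnotations:
    """Locate the Q onset (start of the QRS complex) for each R peak.

    For each R peak, the Q trough is the ECG minimum in the preceding
    ``search_back_s`` window. Walking backward in time from the trough,
    the slope magnitude first rises through the Q downstroke and then
    decays toward baseline; the Q onset is the first sample where it
    falls below ``slope_fraction`` of the window's maximum slope
    magnitude. Beats whose search window leaves the record are dropped
    with a warning.
    """
    r_peaks = np.asarray(r_peaks, dtype=float)
    if r_peaks.size == 0:
        raise ValueError("r_peaks must be non-empty")
    fs = ecg.fs
    slope = np.gradient(ecg.samples) * fs
    back = int(round(search_back_s * fs))
    q_times, kept_r = [], []
    for r in r_peaks:
        r_idx = int(round((r - ecg.t0) * fs))
        lo = r_idx - back
        if lo < 0:
            warnings.warn(f"beat at {r:.3f} s too close to record start; dropped", stacklevel=2)
            continue
        # Q trough: minimum before the R upstroke (exclude the R peak itself)
        hi = max(lo + 1, r_idx - int(round(0.010 * fs)))
        seg = ecg.samples[lo:hi]
        q_idx = lo + int(np.argmin(seg))
        seg_slope = np.abs(slope[lo : q_idx + 1])
        if seg_slope.size < 2:
            continue
        thr = slope_fraction * seg_slope.max()
        onset_idx = None
        in_edge = False
        for k in range(seg_slope.size - 1, -1, -1):  # backward from the trough
            if not in_edge:
                if seg_slope[k] >= thr:
                    in_edge = True
            elif seg_slope[k] < thr:
                onset_idx = lo + k
                break
        if onset_idx is None:
            warnings.warn(f"no Q onset found before beat at {r:.3f} s; dropped", stacklevel=2)
            continue
        q_times.append(ecg.t0 + onset_idx / fs)
        kept_r.append(r)
    return BeatAnnotations(q_onsets=np.asarray(q_times), r_peaks=np.asarray(kept_r))


def heart_rate(beats: BeatAnnotations, window_s: float | None = 10.0) -> SeriesSummary:
    """Instantaneous heart rate 60/RR per beat pair, median summary.

    The summary is the median instantaneous rate over the trailing
    ``window_s`` seconds (or the whole record when ``None``).
    """
    if len(beats) < 2:
        raise ValueError("insufficient beats: need at least 2 R peaks")
    rr = np.diff(beats.r_peaks)
    inst = 60.0 / rr
    mid = beats.r_peaks[1:]
    if window_s is None:
        sel = np.ones_like(inst, dtype=bool)
    else:
        sel = mid >= mid[-1] - window_s
    return SeriesSummary(times=mid, values=inst, summary=float(np.median(inst[sel])))


def detect_s1_s2(
    hs_env: TimeSeries,
    beats: BeatAnnotations,
    s1_window: tuple[float, float] = (0.02, 0.15),
    s2_window: tuple[float, float] = (0.15, 0.45),
    noise_floor_factor: float = 5.0,
) -> SoundAnnotations:
    """Detect S1 and S2 per beat from the heart-sound envelope.

    S1 is the envelope maximum within ``s1_window`` (seconds) after the
    beat's Q onset; S2 the maximum within ``s2_window`` after S1.
    Intensity is the envelope value at each peak. Peaks below
    ``noise_floor_factor`` times the median envelope are flagged
    low-confidence; beats whose windows fall outside the record are
    skipped with a warning.
    """
    fs = hs_env.fs
    n = len(hs_env)
    floor = noise_floor_factor * float(np.median(hs_env.samples))
    rows = []
    for i, q in enumerate(beats.q_onsets):
        lo1 = int(round((q - hs_env.t0 + s1_window[0]) * fs))
        hi1 = int(round((q - hs_env.t0 + s1_window[1]) * fs))
        if lo1 < 0 or hi1 > n or hi1 <= lo1:
            warnings.warn(f"S1 window out of range for beat {i}; skipped", stacklevel=2)
            continue
        k1 = lo1 + int(np.argmax(hs_env.samples[lo1:hi1]))
        t1 = hs_env.t0 + k1 / fs
        lo2 = int(round((t1 - hs_env.t0 + s2_window[0]) * fs))
        hi2 = int(round((t1 - hs_env.t0 + s2_window[1]) * fs))
        if lo2 >= n or hi2 <= lo2:
            warnings.warn(f"S2 window out of range for beat {i}; skipped", stacklevel=2)
            continue
        hi2 = min(hi2, n)
        k2 = lo2 + int(np.argmax(hs_env.samples[lo2:hi2]))
        t2 = hs_env.t0 + k2 / fs
        i1, i2 = float(hs_env.samples[k1]), float(hs_env.samples[k2])
        rows.append((i, t1, t2, i1, i2, i1 < floor, i2 < floor))
    if not rows:
        cols = [np.array([])] * 5 + [np.array([], dtype=bool)] * 2
        return SoundAnnotations(*cols)
    arr = list(zip(*rows))
    return SoundAnnotations(
        beat_index=np.asarray(arr[0], dtype=int),
        s1_time=np.asarray(arr[1]),
        s2_time=np.asarray(arr[2]),
        s1_intensity=np.asarray(arr[3]),
        s2_intensity=np.asarray(arr[4]),
        s1_low_confidence=np.asarray(arr[5], dtype=bool),
        s2_low_confidence=np.asarray(arr[6], dtype=bool),
    )


def emat(beats: BeatAnnotations, sounds: SoundAnnotations) -> SeriesSummary:
    """Electromechanical activation time: Q onset to S1 peak, in ms.

    Beats without a matched sound detection are skipped.
    """
    idx = sounds.beat_index
    valid = idx < len(beats)
    idx = idx[valid]
    values = (sounds.s1_time[valid] - beats.q_onsets[idx]) * 1000.0
    times = sounds.s1_time[valid]
    summary = float(np.median(values)) if values.size else np.nan
    return SeriesSummary(times=times, values=values, summary=summary)


def s1_s2_interval(sounds: SoundAnnotations) -> SeriesSummary:
    """S1-peak to S2-peak interval (INTERVAL) per beat, in ms."""
    values = (sounds.s2_time - sounds.s1_time) * 1000.0
    summary = float(np.median(values)) if values.size else np.nan
    return SeriesSummary(times=sounds.s1_time, values=values, summary=summary)


def segment_breaths(
    lung_env: TimeSeries,
    min_phase_s: float = 0.5,
    enter_factor: float = 1.5,
    exit_factor: float = 1.0,
    smooth_ms: float = 200.0,
) -> BreathTruth:
    """Segment inspiration/expiration phases from the lung-sound envelope.

    Hysteresis thresholding on the smoothed envelope: a phase is entered
    when the envelope exceeds ``enter_factor`` times its median and left
    when it drops below ``exit_factor`` times the median. Alternating
    phases are labeled by loudness (the louder phase of each breath is
    inspiration). Excursions shorter than ``min_phase_s`` are ignored.
    """
    if lung_env.duration < 2.0:
        raise ValueError("need at least 2 s of lung envelope")
    fs = lung_env.fs
    env = _moving_average(lung_env.samples, int(round(smooth_ms / 1000.0 * fs)))
    med = float(np.median(env))
    hi_thr, lo_thr = enter_factor * med, exit_factor * med
    if med == 0 or not np.any(env > hi_thr):
        warnings.warn("no excursions above threshold; empty segmentation", stacklevel=2)
        return BreathTruth([])

    # hysteresis state machine over threshold crossings
    above_hi = env > hi_thr
    above_lo = env > lo_thr
    excursions = []
    active = bool(above_hi[0])
    start = 0
    for k in range(1, env.size):
        if not active and above_hi[k] and not above_hi[k - 1]:
            active, start = True, k
        elif active and not above_lo[k] and above_lo[k - 1]:
            excursions.append((start, k))
            active = False
    if active:
        excursions.append((start, env.size))
    min_len = int(round(min_phase_s * fs))
    excursions = [(a, b) for a, b in excursions if b - a >= min_len]
    if not excursions:
        warnings.warn("no excursions above threshold; empty segmentation", stacklevel=2)
        return BreathTruth([])

    phases = []
    for j, (a, b) in enumerate(excursions):
        exc_mean = float(np.mean(env[a:b]))
        t_a, t_b = lung_env.t0 + a / fs, lung_env.t0 + b / fs
        # the quiet stretch until the next excursion is the opposite phase
        if j + 1 < len(excursions):
            g_a, g_b = b, excursions[j + 1][0]
        else:
            g_a, g_b = b, env.size
        gap_mean = float(np.mean(env[g_a:g_b])) if g_b - g_a >= min_len else -np.inf
        loud_label = "inspiration" if exc_mean >= gap_mean else "expiration"
        quiet_label = "expiration" if loud_label == "inspiration" else "inspiration"
        phases.append((loud_label, t_a, t_b))
        if g_b - g_a >= min_len:
            phases.append((quiet_label, t_b, lung_env.t0 + g_b / fs))
    return BreathTruth(phases)


def compute_cardio_params(
    ecg: TimeSeries,
    heart_env: TimeSeries,
    window_s: float | None = 10.0,
    s1_window: tuple[float, float] = (0.02, 0.15),
    s2_window: tuple[float, float] = (0.15, 0.45),
) -> tuple[CardioParams, BeatAnnotations, SoundAnnotations]:
    """Full derived-parameter chain: ECG landmarks, S1/S2, HR/EMAT/INTERVAL."""
    r = detect_r_peaks(ecg)
    beats = detect_q_onset(ecg, r)
    sounds = detect_s1_s2(heart_env, beats, s1_window=s1_window, s2_window=s2_window)
    hr = heart_rate(beats, window_s=window_s)
    em = emat(beats, sounds)
    iv = s1_s2_interval(sounds)
    s1_int = SeriesSummary(
        times=sounds.s1_time,
        values=sounds.s1_intensity,
        summary=float(np.median(sounds.s1_intensity)) if len(sounds) else np.nan,
    )
    s2_int = SeriesSummary(
        times=sounds.s2_time,
        values=sounds.s2_intensity,
        summary=float(np.median(sounds.s2_intensity)) if len(sounds) else np.nan,
    )
    params = CardioParams(hr_bpm=hr, emat_ms=em, interval_ms=iv, s1_intensity=s1_int, s2_intensity=s2_int)
    return params, beats, sounds
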