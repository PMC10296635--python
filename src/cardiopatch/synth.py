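"""Synthetic, time-synchronized cardiopulmonary signals with known truth.

Generates the signal kinds the patch records — a single-lead ECG, heart
sounds (S1/S2 bursts locked to the ECG), lung sounds (band-limited noise
with a breathing envelope), and two-microphone noisy mixtures — together
with exact ground-truth annotations. Truth is written from the
construction parameters before synthesis and never re-estimated, so the
detection stages can be validated by parameter recovery.

Morphology choices
------------------
* ECG beats are a sum of Gaussian bumps (P, Q, R, S, T) at fixed
  intra-beat offsets; enough to exercise R-peak and Q-onset detection
  without a dynamical heart model.
* The Q onset is defined, in truth, as the start of the Q bump: its
  center minus three standard deviations — a reproducible, sample-exact
  landmark.
* Heart-sound bursts are Gaussian-windowed cosines: S1 about 70 ms wide
  centered at 48 Hz (the dominant heart-sound frequency), S2 about 50 ms
  wide and slightly higher pitched.
* Lung sound is Gaussian noise band-limited to the 300-1800 Hz lung band
  and amplitude-modulated by a breath envelope with inspiration louder
  than expiration, as observed on healthy adults.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import signal as sps

from .core import TimeSeries, StereoRecording
from .filters import lung_band, apply_filter

__all__ = [
    "SynthConfig",
    "BeatAnnotations",
    "SoundTruth",
    "BreathTruth",
    "generate_ecg",
    "generate_heart_sound",
    "generate_lung_sound",
    "mix_two_mic",
]

# Gaussian beat template: (name, center offset from R in s, sigma in s,
# amplitude relative to R). The Q onset landmark is Q center - 3*sigma_Q
# = 70 ms before R, inside the 80 ms backward search used by detection.
_BEAT_BUMPS = (
    ("P", -0.200, 0.025, 0.15),
    ("Q", -0.040, 0.010, -0.10),
    ("R", 0.000, 0.010, 1.00),
    ("S", 0.030, 0.010, -0.20),
    ("T", 0.300, 0.040, 0.30),
)
_Q_OFFSET = -0.040
_Q_SIGMA = 0.010
#: Q onset relative to the R peak (s): start (mean - 3 sigma) of the Q bump.
Q_ONSET_OFFSET = _Q_OFFSET - 3.0 * _Q_SIGMA

# Burst widths: full width ~= 6 sigma.
_S1_SIGMA = 0.070 / 6.0
_S2_SIGMA = 0.050 / 6.0

# Lead-in before the first R peak (room for the P wave and Q onset) and
# tail after the last one (room for T wave and S2).
_LEAD_IN = 0.35
_TAIL = 0.45


@dataclass
class SynthConfig:
    """Generator configuration; defaults reproduce the study conditions.

    All times are seconds from record start, rates in the units named.
    ``emat`` is the Q-onset to S1-peak delay (electromechanical
    activation time); ``s1_s2_interval`` the S1-peak to S2-peak time.
    """

    fs: float = 4000.0              # Hz
    duration: float = 30.0          # s
    hr_bpm: float = 72.0            # beats/min
    hrv_sd: float = 0.005           # s, SD of beat-period jitter
    emat: float = 0.076             # s, Q onset -> S1 peak
    s1_s2_interval: float = 0.300   # s, S1 peak -> S2 peak
    s1_center_freq: float = 48.0    # Hz, dominant heart-sound frequency
    s2_center_freq: float = 60.0    # Hz
    s1_amp: float = 1.0             # acoustic units
    s2_amp: float = 0.6             # acoustic units
    ecg_pp_amp: float = 300.0       # mV peak-to-peak (as displayed)
    breath_rate: float = 15.0       # breaths/min
    insp_exp_amp_ratio: float = 2.0 # inspiration/expiration amplitude, > 1
    noise_kind: str = "sinusoidal"  # white | sinusoidal | babble-like
    noise_freq_hz: float = 50.0     # Hz, for sinusoidal (mains-like) noise
    noise_snr_db: float = 0.0       # input SNR at the primary microphone
    channel_ir_length: int = 8      # taps of the noise-path FIR
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fs", "duration", "hr_bpm", "breath_rate"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.hrv_sd < 0 or self.emat < 0:
            raise ValueError("hrv_sd and emat must be non-negative")
        if not self.s1_s2_interval > 0:
            raise ValueError("s1_s2_interval must be positive")
        if not self.insp_exp_amp_ratio > 1:
            raise ValueError("insp_exp_amp_ratio must exceed 1 (inspiration is louder)")
        if self.noise_kind not in ("white", "sinusoidal", "babble-like"):
            raise ValueError(f"unknown noise_kind {self.noise_kind!r}")
        if self.channel_ir_length < 1:
            raise ValueError("channel_ir_length must be >= 1")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic stream per generator stage."""
        return np.random.default_rng([int(self.seed) % 2**31, stream])

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class BeatAnnotations:
    """Per-beat ECG landmarks: Q onsets and R peaks, in seconds."""

    q_onsets: np.ndarray
    r_peaks: np.ndarray

    def __post_init__(self) -> None:
        self.q_onsets = np.asarray(self.q_onsets, dtype=float)
        self.r_peaks = np.asarray(self.r_peaks, dtype=float)
        if self.q_onsets.shape != self.r_peaks.shape:
            raise ValueError("q_onsets and r_peaks must pair up")
        if np.any(np.diff(self.q_onsets) <= 0) or np.any(np.diff(self.r_peaks) <= 0):
            raise ValueError("annotations must be strictly increasing")
        lead = self.r_peaks - self.q_onsets
        if self.q_onsets.size and (np.any(lead < 0) or np.any(lead > 0.080 + 1e-12)):
            raise ValueError("each Q onset must precede its R peak by 0-80 ms")

    def __len__(self) -> int:
        return self.r_peaks.size


@dataclass
class SoundTruth:
    """Exact per-beat S1/S2 construction times and amplitudes.

    ``truncated`` flags beats whose burst ran past the record end and was
    cut short in the rendered signal (the truth times are still listed).
    """

    s1_peak_time: np.ndarray
    s2_peak_time: np.ndarray
    s1_amp: np.ndarray
    s2_amp: np.ndarray
    truncated: np.ndarray

    def __post_init__(self) -> None:
        for name in ("s1_peak_time", "s2_peak_time", "s1_amp", "s2_amp"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.truncated = np.asarray(self.truncated, dtype=bool)
        if np.any(self.s2_peak_time <= self.s1_peak_time):
            raise ValueError("S1 must precede S2 within each beat")

    def __len__(self) -> int:
        return self.s1_peak_time.size


@dataclass
class BreathTruth:
    """Breath-phase intervals: (phase, start, end), half-open [start, end)."""

    phases: list = field(default_factory=list)  # (str, float, float)

    def __post_init__(self) -> None:
        prev_end = -np.inf
        for phase, start, end in self.phases:
            if phase not in ("inspiration", "expiration"):
                raise ValueError(f"unknown phase {phase!r}")
            if not start < end:
                raise ValueError("phase interval must have start < end")
            if start < prev_end:
                raise ValueError("phase intervals must be non-overlapping, increasing")
            prev_end = end

    def inspirations(self) -> list:
        return [(s, e) for p, s, e in self.phases if p == "inspiration"]

    def expirations(self) -> list:
        return [(s, e) for p, s, e in self.phases if p == "expiration"]

    def __len__(self) -> int:
        return len(self.phases)


def _beat_times(cfg: SynthConfig) -> np.ndarray:
    """R-peak times: lead-in, then jittered beat periods until the tail."""
    if cfg.duration < _LEAD_IN + _TAIL + 60.0 / cfg.hr_bpm:
        raise ValueError(
            f"too short: duration {cfg.duration} s cannot hold one beat at "
            f"{cfg.hr_bpm} bpm with lead-in/tail margins"
        )
    rng = cfg.rng(stream=1)
    mean_period = 60.0 / cfg.hr_bpm
    r_peaks = []
    t = _LEAD_IN
    while t <= cfg.duration - _TAIL:
        r_peaks.append(t)
        period = mean_period + (rng.normal(0.0, cfg.hrv_sd) if cfg.hrv_sd > 0 else 0.0)
        t += max(period, 0.3)  # floor keeps periods physiologic under heavy jitter
    return np.asarray(r_peaks)


def _add_gaussian(out: np.ndarray, fs: float, center: float, sigma: float, amp: float) -> None:
    """Add a Gaussian bump in place, evaluated only on a +-5 sigma slice."""
    lo = max(0, int(np.floor((center - 5 * sigma) * fs)))
    hi = min(out.size, int(np.ceil((center + 5 * sigma) * fs)) + 1)
    if hi <= lo:
        return
    t = np.arange(lo, hi) / fs
    out[lo:hi] += amp * np.exp(-0.5 * ((t - center) / sigma) ** 2)


def generate_ecg(cfg: SynthConfig) -> tuple[TimeSeries, BeatAnnotations]:
    """Synthesize a single-lead ECG with exact beat annotations.

    Each beat is a sum of Gaussian bumps (P, Q, R, S, T) at fixed offsets
    from its R peak; the whole record is rescaled so its peak-to-peak
    amplitude equals ``cfg.ecg_pp_amp`` (mV). Returned annotations are
    the construction times: R-peak times and Q onsets (Q center - 3
    sigma).
    """
    r_peaks = _beat_times(cfg)
    n = int(round(cfg.duration * cfg.fs))
    ecg = np.zeros(n)
    for r in r_peaks:
        for _, offset, sigma, amp in _BEAT_BUMPS:
            _add_gaussian(ecg, cfg.fs, r + offset, sigma, amp)
    pp = ecg.max() - ecg.min()
    ecg *= cfg.ecg_pp_amp / pp
    ann = BeatAnnotations(q_onsets=r_peaks + Q_ONSET_OFFSET, r_peaks=r_peaks)
    return TimeSeries(ecg, cfg.fs), ann


def _add_burst(
    out: np.ndarray, fs: float, center: float, sigma: float, amp: float, freq: float
) -> bool:
    """Add a Gaussian-windowed cosine burst in place; True if truncated."""
    lo_t, hi_t = center - 5 * sigma, center + 5 * sigma
    lo = max(0, int(np.floor(lo_t * fs)))
    hi = min(out.size, int(np.ceil(hi_t * fs)) + 1)
    if hi <= lo:
        return True
    t = np.arange(lo, hi) / fs
    out[lo:hi] += (
        amp * np.exp(-0.5 * ((t - center) / sigma) ** 2) * np.cos(2 * np.pi * freq * (t - center))
    )
    return hi_t * fs > out.size  # burst support runs past the record end


def generate_heart_sound(
    beats: BeatAnnotations, cfg: SynthConfig
) -> tuple[TimeSeries, SoundTruth]:
    """Synthesize heart sounds locked to ECG beats.

    For each beat, S1 is a Gaussian-windowed cosine at
    ``cfg.s1_center_freq`` centered ``cfg.emat`` after the beat's Q
    onset; S2 follows ``cfg.s1_s2_interval`` later at
    ``cfg.s2_center_freq``. Truth records the construction times and
    amplitudes exactly; bursts running past the record end are truncated
    in the signal and flagged in truth.
    """
    if len(beats) == 0:
        raise ValueError("beats must be non-empty")
    n = int(round(cfg.duration * cfg.fs))
    hs = np.zeros(n)
    s1_times = beats.q_onsets + cfg.emat
    s2_times = s1_times + cfg.s1_s2_interval
    truncated = np.zeros(len(beats), dtype=bool)
    for i, (t1, t2) in enumerate(zip(s1_times, s2_times)):
        tr1 = _add_burst(hs, cfg.fs, t1, _S1_SIGMA, cfg.s1_amp, cfg.s1_center_freq)
        tr2 = False
        if cfg.s2_amp > 0:
            tr2 = _add_burst(hs, cfg.fs, t2, _S2_SIGMA, cfg.s2_amp, cfg.s2_center_freq)
        elif t2 * cfg.fs > n:
            tr2 = True
        truncated[i] = tr1 or tr2
    truth = SoundTruth(
        s1_peak_time=s1_times,
        s2_peak_time=s2_times,
        s1_amp=np.full(len(beats), cfg.s1_amp),
        s2_amp=np.full(len(beats), cfg.s2_amp),
        truncated=truncated,
    )
    return TimeSeries(hs, cfg.fs), truth


# Fraction of each breath cycle spent inspiring; the remainder is
# expiration (passive expiration is longer in adults).
_INSP_FRACTION = 0.4
_RAMP_S = 0.05  # raised-cosine ramp at phase boundaries


def generate_lung_sound(cfg: SynthConfig) -> tuple[TimeSeries, BreathTruth]:
    """Synthesize lung sound: band-limited noise under a breath envelope.

    Gaussian noise is band-limited to the 300-1800 Hz lung band, then
    amplitude-modulated: inspiration intervals carry
    ``cfg.insp_exp_amp_ratio`` times the expiration amplitude. Truth
    lists the exact phase intervals.
    """
    rng = cfg.rng(stream=2)
    n = int(round(cfg.duration * cfg.fs))
    noise = rng.standard_normal(n)
    band = lung_band(fs=cfg.fs)
    carrier = apply_filter(TimeSeries(noise, cfg.fs), band, zero_phase=True).samples

    cycle = 60.0 / cfg.breath_rate
    insp_len = _INSP_FRACTION * cycle
    amp = np.ones(n)
    phases = []
    t = 0.0
    while t < cfg.duration:
        insp_end = min(t + insp_len, cfg.duration)
        i0, i1 = int(round(t * cfg.fs)), int(round(insp_end * cfg.fs))
        amp[i0:i1] = cfg.insp_exp_amp_ratio
        phases.append(("inspiration", t, insp_end))
        if insp_end < cfg.duration:
            exp_end = min(t + cycle, cfg.duration)
            phases.append(("expiration", insp_end, exp_end))
        t += cycle
    # soften phase boundaries so the envelope is physiological, not a gate
    ramp = int(round(_RAMP_S * cfg.fs))
    if ramp > 1:
        win = np.hanning(2 * ramp + 1)
        amp = np.convolve(amp, win / win.sum(), mode="same")
    return TimeSeries(carrier * amp, cfg.fs), BreathTruth(phases)


def _draw_noise(cfg: SynthConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    if cfg.noise_kind == "white":
        return rng.standard_normal(n)
    if cfg.noise_kind == "sinusoidal":
        phase = rng.uniform(0, 2 * np.pi)
        t = np.arange(n) / cfg.fs
        return np.sin(2 * np.pi * cfg.noise_freq_hz * t + phase)
    # babble-like: broadband noise shaped to the speech-ish mid band
    raw = rng.standard_normal(n)
    sos = sps.butter(4, [100.0, 1000.0], btype="bandpass", fs=cfg.fs, output="sos")
    return sps.sosfilt(sos, raw)


def mix_two_mic(clean: TimeSeries, cfg: SynthConfig) -> tuple[StereoRecording, TimeSeries]:
    """Mix a clean signal with ambient noise seen through two microphones.

    The reference microphone observes the noise directly; the primary
    microphone observes ``clean`` plus the noise convolved with a random
    FIR channel (``cfg.channel_ir_length`` taps, unit leading tap). The
    noise is scaled so the primary-channel input SNR equals
    ``cfg.noise_snr_db``. Also returns the noise as seen by the primary
    so the true SNR is computable.
    """
    if clean.fs != cfg.fs:
        raise ValueError(f"clean.fs {clean.fs} != cfg.fs {cfg.fs}")
    if not np.isfinite(cfg.noise_snr_db):
        raise ValueError("noise_snr_db must be finite")
    rng = cfg.rng(stream=3)
    n = len(clean)
    noise = _draw_noise(cfg, n, rng)
    h = np.zeros(cfg.channel_ir_length)
    h[0] = 1.0
    if cfg.channel_ir_length > 1:
        decay = 0.5 ** np.arange(1, cfg.channel_ir_length)
        h[1:] = 0.5 * rng.standard_normal(cfg.channel_ir_length - 1) * decay
    noise_in_primary = sps.lfilter(h, [1.0], noise)

    p_clean = float(np.mean(clean.samples**2))
    p_noise = float(np.mean(noise_in_primary**2))
    if p_noise == 0:
        raise ValueError("drawn noise has zero power")
    gain = np.sqrt(p_clean / (p_noise * 10.0 ** (cfg.noise_snr_db / 10.0)))
    noise_in_primary *= gain
    noise *= gain

    primary = clean.copy_with(clean.samples + noise_in_primary)
    reference = clean.copy_with(noise)
    return StereoRecording(primary=primary, reference=reference), clean.copy_with(noise_in_primary)
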