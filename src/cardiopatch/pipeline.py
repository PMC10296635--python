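"""The full processing chain of the patch, offline or block-streaming.

Order of stages mirrors the device: adaptive noise cancellation of the
stethoscope audio against the ambient microphone, Chebyshev band-pass
separation into heart (25-100 Hz) and lung (300-1800 Hz) channels,
envelope and STFT spectrogram, ECG-gated detections, and the derived
parameters (HR, EMAT, INTERVAL, S1/S2 intensities).

In streaming mode the ANC and the causal band filters are run over
fixed-size blocks with their state (adaptive weights, reference history,
filter sections) carried across block boundaries, so the assembled
output is sample-identical to a single causal pass; detections then run
on the assembled record, as the display software would.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .anc import ANCResult, LMSConfig, LMSState, lms_denoise, snr_db, snr_improvement
from .core import StereoRecording, TimeSeries
from .features import (
    CardioParams,
    SoundAnnotations,
    compute_cardio_params,
    envelope,
    segment_breaths,
)
from .filters import apply_filter, causal_initial_state, design_bandpass
from .spectral import Spectrogram, stft_spectrogram
from .synth import BeatAnnotations, BreathTruth

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Resolved configuration for one run of the chain."""

    fs: float = 4000.0
    anc_enabled: bool = True
    lms: LMSConfig = field(default_factory=LMSConfig)
    heart_band: tuple[float, float] = (25.0, 100.0)
    lung_band: tuple[float, float] = (300.0, 1800.0)
    filter_order: int = 4
    ripple_db: float = 0.5
    zero_phase: bool = True           # offline analysis; False = causal/device mode
    stream: bool = False              # block-wise causal processing
    block_samples: int = 1024         # 256 ms at 4 kHz
    envelope_method: str = "analytic"
    envelope_smooth_ms: float = 20.0
    s1_window: tuple[float, float] = (0.02, 0.15)
    s2_window: tuple[float, float] = (0.15, 0.45)
    hr_window_s: float | None = 10.0
    fft_size: int = 2048
    hop: int | None = None
    window: str = "hann"
    segment_lung: bool = True

    def __post_init__(self) -> None:
        if self.block_samples < self.lms.order:
            raise ValueError("block_samples must be >= LMS order")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PipelineResult:
    """All artifacts of one run, from denoised audio to panel summaries."""

    denoised: TimeSeries
    heart: TimeSeries
    lung: TimeSeries
    heart_env: TimeSeries
    lung_env: TimeSeries
    params: CardioParams
    beats: BeatAnnotations
    sounds: SoundAnnotations
    breaths: BreathTruth
    spectrogram: Spectrogram
    anc: ANCResult | None = None
    snr_metrics: dict | None = None

    def summary_dict(self) -> dict:
        out = self.params.summary_dict()
        if self.snr_metrics:
            out.update(self.snr_metrics)
        return out


def _blocks(n: int, size: int):
    for lo in range(0, n, size):
        yield lo, min(lo + size, n)


def run_pipeline(
    ecg: TimeSeries,
    primary: TimeSeries,
    reference: TimeSeries | None = None,
    cfg: PipelineConfig | None = None,
    clean_for_snr: TimeSeries | None = None,
) -> PipelineResult:
    """Execute ANC -> band filters -> envelope/STFT -> detections -> parameters.

    ``reference`` is required when ANC is enabled. When the true noise
    component of the primary channel is known (synthetic studies), pass
    it as ``clean_for_snr`` via the clean signal to get before/after SNR
    metrics; otherwise SNR reporting is skipped.
    """
    cfg = cfg or PipelineConfig()
    for name, ts in (("ecg", ecg), ("primary", primary)):
        if ts.fs != cfg.fs:
            raise ValueError(f"{name} sampled at {ts.fs} Hz, pipeline expects {cfg.fs} Hz")

    # --- stage 1: adaptive noise cancellation ---------------------------
    anc_result = None
    if cfg.anc_enabled:
        if reference is None:
            raise ValueError("ANC enabled but channel 'reference' is missing")
        rec = StereoRecording(primary=primary, reference=reference)
        if cfg.stream:
            state = LMSState(cfg.lms)
            pieces = []
            for lo, hi in _blocks(len(rec), cfg.block_samples):
                block = StereoRecording(
                    primary=TimeSeries(rec.primary.samples[lo:hi], cfg.fs),
                    reference=TimeSeries(rec.reference.samples[lo:hi], cfg.fs),
                )
                pieces.append(lms_denoise(block, cfg.lms, state=state).denoised.samples)
            denoised = primary.copy_with(np.concatenate(pieces))
            anc_result = ANCResult(
                denoised=denoised, weights_final=state.weights.copy(), mse_curve=np.array([])
            )
        else:
            anc_result = lms_denoise(rec, cfg.lms)
            denoised = anc_result.denoised
    else:
        denoised = primary

    # --- stage 2: Chebyshev band separation -----------------------------
    heart_spec = design_bandpass(*cfg.heart_band, fs=cfg.fs, order=cfg.filter_order, ripple_db=cfg.ripple_db)
    lung_spec = design_bandpass(*cfg.lung_band, fs=cfg.fs, order=cfg.filter_order, ripple_db=cfg.ripple_db)
    zero_phase = cfg.zero_phase and not cfg.stream
    if cfg.stream:
        heart_parts, lung_parts = [], []
        zh, zl = causal_initial_state(heart_spec), causal_initial_state(lung_spec)
        for lo, hi in _blocks(len(denoised), cfg.block_samples):
            block = TimeSeries(denoised.samples[lo:hi], cfg.fs)
            hpart, zh = apply_filter(block, heart_spec, zero_phase=False, zi=zh)
            lpart, zl = apply_filter(block, lung_spec, zero_phase=False, zi=zl)
            heart_parts.append(hpart.samples)
            lung_parts.append(lpart.samples)
        heart = denoised.copy_with(np.concatenate(heart_parts))
        lung = denoised.copy_with(np.concatenate(lung_parts))
    else:
        heart = apply_filter(denoised, heart_spec, zero_phase=zero_phase)
        lung = apply_filter(denoised, lung_spec, zero_phase=zero_phase)

    # --- stage 3: envelopes and spectrogram -----------------------------
    heart_env = envelope(heart, method=cfg.envelope_method, smooth_ms=cfg.envelope_smooth_ms)
    lung_env = envelope(lung, method="rms", smooth_ms=max(cfg.envelope_smooth_ms, 50.0))
    spec = stft_spectrogram(heart, fft_size=cfg.fft_size, hop=cfg.hop, window=cfg.window)

    # --- stage 4: detections and derived parameters ---------------------
    params, beats, sounds = compute_cardio_params(
        ecg,
        heart_env,
        window_s=cfg.hr_window_s,
        s1_window=cfg.s1_window,
        s2_window=cfg.s2_window,
    )
    if cfg.segment_lung:
        try:
            breaths = segment_breaths(lung_env)
        except ValueError:
            breaths = BreathTruth([])
    else:
        breaths = BreathTruth([])

    # --- optional SNR evaluation (synthetic studies) --------------------
    snr_metrics = None
    if clean_for_snr is not None and cfg.anc_enabled and reference is not None:
        noise_before = primary.copy_with(primary.samples - clean_for_snr.samples)
        noise_after = primary.copy_with(denoised.samples - clean_for_snr.samples)
        before = snr_db(clean_for_snr, noise_before)
        after = snr_db(clean_for_snr, noise_after)
        snr_metrics = {"snr_before_db": before, "snr_after_db": after}
        snr_metrics.update(snr_improvement(before, after))

    return PipelineResult(
        denoised=denoised,
        heart=heart,
        lung=lung,
        heart_env=heart_env,
        lung_env=lung_env,
        params=params,
        beats=beats,
        sounds=sounds,
        breaths=breaths,
        spectrogram=spec,
        anc=anc_result,
        snr_metrics=snr_metrics,
    )
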