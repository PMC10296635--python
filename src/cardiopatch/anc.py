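"""LMS adaptive noise cancellation and SNR metrics.

The patch carries two microphones: the stethoscope microphone (primary,
wanted sounds plus ambient noise) and an ambient microphone (reference,
noise only). An adaptive FIR filter predicts the noise component of the
primary channel from the reference and subtracts it; the error signal

    y[n] = w . x[n]
    e[n] = primary[n] - y[n]
    w   <- w + mu * e[n] * x[n]            (LMS)
    w   <- w + mu / (eps + ||x[n]||^2) * e[n] * x[n]   (NLMS)

is the denoised output, where x[n] holds the most recent L reference
samples. Weights adapt once per sample, in order, with zero-padded
start-up history — the streaming semantics of the device.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import StereoRecording, TimeSeries

__all__ = ["LMSConfig", "ANCResult", "lms_denoise", "snr_db", "snr_improvement"]


@dataclass
class LMSConfig:
    """Adaptive-filter configuration.

    ``order`` is the number of FIR taps L; ``step`` the adaptation step
    mu. ``normalized`` selects the NLMS variant (default), which divides
    the step by the instantaneous input power and is insensitive to the
    reference signal's scale. For plain LMS the stability bound
    ``mu < 2 / (L * mean reference power)`` is checked at run time.
    """

    order: int = 32
    step: float = 0.01
    normalized: bool = True
    eps: float = 1e-8
    init_weights: np.ndarray | None = None
    keep_weight_history: bool = False

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if not self.step > 0:
            raise ValueError("step must be positive")
        if self.init_weights is not None:
            self.init_weights = np.asarray(self.init_weights, dtype=float)
            if self.init_weights.shape != (self.order,):
                raise ValueError("init_weights must have exactly `order` entries")


@dataclass
class ANCResult:
    """Output of the adaptive canceller.

    ``denoised`` is the error signal e — in the ANC configuration that IS
    the cleaned output. ``mse_curve`` is the per-sample squared error;
    ``weight_history`` is populated only when requested (memory contract).
    """

    denoised: TimeSeries
    weights_final: np.ndarray
    mse_curve: np.ndarray
    weight_history: np.ndarray | None = None


class LMSState:
    """Adaptation state carried across streaming blocks."""

    def __init__(self, cfg: LMSConfig):
        self.weights = (
            np.zeros(cfg.order) if cfg.init_weights is None else cfg.init_weights.copy()
        )
        self.x_tail = np.zeros(cfg.order - 1)  # reference history before the block


def _lms_block(
    primary: np.ndarray,
    reference: np.ndarray,
    cfg: LMSConfig,
    state: LMSState,
    keep_history: bool,
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Per-sample LMS/NLMS recursion over one block, updating state."""
    L = cfg.order
    n = primary.size
    # x_ext[k : k+L] reversed = the last L reference samples at time k
    x_ext = np.concatenate([state.x_tail, reference])
    w = state.weights
    e = np.empty(n)
    history = np.empty((n, L)) if keep_history else None
    mu = cfg.step
    with np.errstate(over="ignore", invalid="ignore"):  # divergence is caught explicitly
        for k in range(n):
            x = x_ext[k : k + L][::-1]
            y = float(w @ x)
            err = primary[k] - y
            if cfg.normalized:
                w = w + (mu / (cfg.eps + float(x @ x))) * err * x
            else:
                w = w + mu * err * x
            if not np.all(np.isfinite(w)):
                raise FloatingPointError(f"diverged at sample {k}")
            e[k] = err
            if keep_history:
                history[k] = w
    state.weights = w
    if L > 1:
        state.x_tail = x_ext[n:].copy() if n >= L - 1 else x_ext[-(L - 1):].copy()
    return e, w, history


def lms_denoise(
    rec: StereoRecording, cfg: LMSConfig | None = None, state: LMSState | None = None
) -> ANCResult:
    """Cancel reference-correlated noise from the primary channel.

    Returns the error signal as the denoised output. Passing ``state``
    carries weights and reference history across consecutive blocks for
    streaming operation; by default adaptation starts from the
    configured initial weights with zero-padded history.
    """
    cfg = cfg or LMSConfig()
    if len(rec) < cfg.order:
        raise ValueError(f"recording shorter than filter order ({len(rec)} < {cfg.order})")
    if not cfg.normalized:
        p_ref = float(np.mean(rec.reference.samples**2))
        if p_ref > 0 and cfg.step >= 2.0 / (cfg.order * p_ref):
            warnings.warn(
                f"step {cfg.step} violates the LMS stability bound "
                f"2/(L*P_ref) = {2.0 / (cfg.order * p_ref):.3g}; "
                "consider the normalized variant (NLMS)",
                stacklevel=2,
            )
    state = state or LMSState(cfg)
    e, w, history = _lms_block(
        rec.primary.samples, rec.reference.samples, cfg, state, cfg.keep_weight_history
    )
    return ANCResult(
        denoised=rec.primary.copy_with(e),
        weights_final=w.copy(),
        mse_curve=e**2,
        weight_history=history,
    )


def snr_db(signal_part: TimeSeries, noise_part: TimeSeries) -> float:
    """Signal-to-noise ratio 10*log10(sum s^2 / sum n^2) in dB."""
    if len(signal_part) != len(noise_part):
        raise ValueError("signal and noise parts must have equal length")
    p_sig = float(np.sum(signal_part.samples**2))
    p_noise = float(np.sum(noise_part.samples**2))
    if p_noise == 0:
        warnings.warn("zero noise power: SNR is +inf", stacklevel=2)
        return np.inf
    return 10.0 * np.log10(p_sig / p_noise)


def snr_improvement(before_db: float, after_db: float) -> dict:
    """Relative SNR improvement, reported under both plausible conventions.

    There is no single convention for quoting an SNR improvement as a
    percentage, so both are returned alongside the raw dB delta:

    * ``percent_db_ratio`` — (after - before) / |before| * 100, i.e. the
      relative change of the dB figure itself;
    * ``percent_power_ratio`` — relative change of the linear
      signal-to-noise power ratio, (10^(after/10) - 10^(before/10)) /
      10^(before/10) * 100.
    """
    if not (np.isfinite(before_db) and np.isfinite(after_db)):
        raise ValueError("SNR values must be finite")
    delta = after_db - before_db
    pct_db = 100.0 * delta / abs(before_db) if before_db != 0 else np.inf * np.sign(delta) if delta else 0.0
    pct_power = 100.0 * (10.0 ** (delta / 10.0) - 1.0)
    return {
        "delta_db": delta,
        "percent_db_ratio": pct_db,
        "percent_power_ratio": pct_power,
    }
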