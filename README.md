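# cardiopatch

Signal-processing chain of a wearable cardiopulmonary stethoscope patch,
as a tested Python library with a thin CLI. The device this models
records three synchronized channels at 4 kHz — a single-lead ECG, a
stethoscope microphone (heart + lung sounds + ambient noise), and an
ambient reference microphone — and derives the parameters a bedside
monitor displays. This package implements that chain in software, for
engineers and researchers working on auscultation devices and
phonocardiogram/ECG analysis:

1. **Adaptive noise cancellation (ANC).** An L-tap FIR filter driven by
   the (N)LMS update cancels the ambient noise from the stethoscope
   channel using the reference microphone:
   `y[n] = wᵀx[n]`, `e[n] = d[n] − y[n]`, `w ← w + μ·e[n]·x[n]`
   (NLMS: `μ → μ/(ε + ‖x[n]‖²)`), where `x[n]` holds the last L
   reference samples and the error `e` is the denoised output.
2. **Band separation.** Chebyshev type-I band-passes split the denoised
   audio into the heart band (25–100 Hz, dominant S1 energy near 48 Hz)
   and the lung band (300–1800 Hz), applied as second-order sections.
3. **Spectrogram.** Short-time Fourier transform of the heart channel:
   FFT size 2048 at 4 kHz ⇒ one frame every 2048/4000 = 512 ms,
   frequency resolution 4000/2048 ≈ 1.95 Hz.
4. **Derived parameters.** R peaks and Q onsets from the ECG; S1/S2
   peaks and intensities from the heart-sound envelope, gated by the
   ECG; heart rate HR = 60/RR; the S1→S2 interval (INTERVAL); and the
   electromechanical activation time EMAT = Q-wave onset → S1 peak, an
   index of cardiac contractility. Lung-sound envelopes are segmented
   into inspiration/expiration (inspiration is louder in adults).

Because clinical recordings from such patches are not generally
available, the package ships a first-class synthetic-data module
(`cardiopatch.synth`) that generates beat-synchronous ECG, ECG-locked
S1/S2 bursts, breath-modulated lung noise and two-microphone noisy
mixtures with exact ground truth, so every detector can be validated by
parameter recovery.

## Worked example

```bash
python examples/04_derive_cardio_params.py
```

generates a 30-s synthetic recording (72 bpm, EMAT 76 ms, S1–S2 interval
300 ms, sinusoidal ambient noise at 0 dB SNR), runs the full chain, and
prints:

```
beats detected: 35
heart rate:       71.6 bpm   (configured 72.0)
EMAT:             73.8 ms    (configured 76.0)
S1-S2 interval:  301.8 ms    (configured 300.0)
S1 intensity:   0.623  S2 intensity: 0.377 (envelope units)
ANC SNR gain:     24.5 dB
```

The heart rate, EMAT and INTERVAL are medians over per-beat estimates;
they recover the configured truth to within ~1 bpm / ~2.5 ms / ~2 ms
despite the 0 dB input noise, and the ANC lifts the stethoscope-channel
SNR by ~24 dB. The other examples (`examples/01…05`) each demonstrate
one capability: simulation, ANC, band separation + spectrogram, derived
parameters, and breath segmentation.

The same chain is scriptable from a shell:

```bash
cardiopatch --out-dir rec simulate --duration 30 --seed 1
cardiopatch --out-dir out run rec/recording.wav
```

which writes per-beat annotations (`beats.csv`), breath phases
(`breaths.csv`) and the panel summary (`summary.json`), every file
tagged with the hash of the resolved configuration.

## Layout

- `src/cardiopatch/` — `synth` (generators + truth), `anc` (LMS/NLMS,
  SNR metrics), `filters` (Chebyshev band-passes), `spectral` (STFT),
  `features` (detectors and derived parameters), `pipeline` (the chain,
  offline and block-streaming), `io` (WAV/CSV), `cli`.
- `examples/` — one short narrative script per capability.
- `docs/methods.md` — models, assumptions, parameter choices, known
  limitations.
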