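# Methods

This note documents the models behind `cardiopatch`, the parameters that
matter, what the synthetic data does and does not emulate, and the
numerical choices a maintainer would want to know.

## Signal model

The device records three time-synchronized channels at a common
sampling rate (default 4 kHz): a single-lead ECG, a primary microphone
at the stethoscope head, and an ambient reference microphone. The
primary channel is modeled as

    primary[n] = heart[n] + lung[n] + (h * noise)[n]
    reference[n] = noise[n]

where `h` is an unknown FIR acoustic path from the ambient field to the
stethoscope head. Heart sounds occupy roughly 24–144 Hz with dominant
energy near 48 Hz; lung sounds occupy 300–1800 Hz after band limiting.
The two bands are disjoint, which is what makes separation by band-pass
filtering well posed.

## Adaptive noise cancellation

`anc.lms_denoise` implements the classic two-microphone canceller: an
L-tap FIR filter driven by LMS or NLMS predicts the noise component of
the primary channel from the reference, and the prediction error is the
cleaned output. Updates are strictly per-sample and causal with
zero-padded start-up history, matching streaming operation on the
device; a vectorized variant was deliberately not used so that the
recursion is bit-for-bit the textbook one (the test suite checks it
against an independently coded scalar loop).

Parameters:

- `order` (L, default 32 taps = 8 ms at 4 kHz): long enough to model a
  short acoustic path plus a phase/amplitude mismatch; short enough to
  adapt within a second.
- `step` (μ, default 0.01) with `normalized=True` (NLMS): the
  normalized update is insensitive to the reference scale and stable
  for 0 < μ < 2. 0.01 trades convergence speed (~1 s) against
  misadjustment. For plain LMS the stability bound μ < 2/(L·P_ref) is
  checked at run time and a warning suggests NLMS when violated.
- `eps` (1e−8): regularizer of the NLMS power estimate.

SNR is `10·log10(Σsignal²/Σnoise²)`. A percentage "improvement" of SNR
has no unique convention, so `snr_improvement` reports the raw dB delta
together with both plausible readings (relative change of the dB figure
and relative change of the linear power ratio) and the caller chooses.

## Band separation

Chebyshev type-I band-passes, order 4, 0.5 dB passband ripple, designed
with `scipy.signal.cheby1` and applied as second-order sections — the
narrow heart band (25–100 Hz at 4 kHz) is numerically fragile in
transfer-function form. Type I keeps the stopband monotone and is the
common reading of "a Chebyshev digital filter"; type, order and ripple
are all exposed. Offline analysis defaults to forward–backward
(zero-phase) filtering so that band filtering adds no group delay to
event timings; streaming mode uses a single causal pass with filter
state carried across blocks, which is sample-exact to an unblocked
causal pass.

## Spectrogram

One-sided magnitude STFT. Defaults follow the display software this
models: FFT size 2048 at 4 kHz, non-overlapping frames (hop = FFT
size), i.e. one frame per 512 ms and 1.953125 Hz bin spacing. The
window defaults to Hann for display; a rectangular window is available
and is what the Parseval identity is tested with. Magnitudes are stored
linearly; dB conversion (floored at −120 dB) is a display concern.

## Detection chain

R peaks: band-pass 5–30 Hz → square → 150 ms moving-window integration
→ peak picking with a 250 ms refractory period and an adaptive
threshold (a fraction of the typical strong-candidate height, so the
detector is amplitude-scale invariant) → refinement to the local ECG
maximum. Q onset: within the 80 ms before each R peak, find the Q
trough, then walk backward; the onset is where the slope magnitude,
after rising through the Q downstroke, first falls below 5% of the
search segment's maximum slope. For a Gaussian-shaped Q wave this
criterion lands at ≈3σ before the Q center, i.e. at the morphological
start of the wave, independent of the wave's width or depth.

S1/S2: the heart-band envelope (analytic-signal magnitude, 20 ms
moving-average smoothing) is searched in physiologic windows — S1 in
20–150 ms after the Q onset, S2 in 150–450 ms after S1; intensity is
the envelope value at the peak (relative units). Peaks below 5× the
median envelope are flagged low-confidence rather than dropped. EMAT is
(S1 peak − Q onset), INTERVAL is (S2 peak − S1 peak), HR is 60/RR; all
summaries are medians, chosen over means for robustness to missed
beats. Windowed and per-beat values are both emitted because a display
device may show either.

Breath segmentation: hysteresis thresholding of the smoothed lung
envelope (enter a phase at 1.5× the median envelope, leave at 1.0×),
minimum phase length 0.5 s; of each excursion/quiet-stretch pair the
louder is labeled inspiration, encoding the physiological fact that
inspiration is louder at the chest wall in adults.

## Synthetic data

The generator (`synth`) writes ground truth from its construction
parameters *before* rendering, never re-estimating it.

- **ECG**: each beat is a sum of five Gaussian bumps (P, Q, R, S, T) at
  fixed offsets from the R peak; the record is rescaled so the
  peak-to-peak amplitude equals the configured value (default 300 mV,
  the amplitude the modeled device displays). The truth Q onset is
  defined as the Q-bump center − 3σ — a reproducible, sample-exact
  landmark. Beat periods are 60/HR plus Gaussian jitter (default SD
  5 ms).
- **Heart sounds**: Gaussian-windowed cosines; S1 ≈ 70 ms wide at 48 Hz
  centered EMAT (default 76 ms) after each Q onset, S2 ≈ 50 ms wide at
  60 Hz following by the configured interval (default 300 ms).
- **Lung sounds**: Gaussian noise band-limited to 300–1800 Hz,
  amplitude-modulated by a breath envelope (default 15 breaths/min,
  inspiration 40% of the cycle and 2× the expiration amplitude, 50 ms
  raised-cosine ramps at phase boundaries).
- **Two-microphone mixing**: ambient noise (white, 50 Hz sinusoidal —
  the default, emulating mains-like interference — or band-shaped
  "babble-like") reaches the primary microphone through a random FIR
  with a unit leading tap and decaying random taps (default 8), scaled
  so the primary-channel input SNR equals the configured value
  (default 0 dB). The noise-as-seen-by-the-primary is returned so true
  SNR is computable.

What this does *not* emulate: real QRS morphology variation, ectopy and
artifact; murmurs and adventitious lung sounds; respiratory modulation
of heart sounds; transducer and amplifier coloration; non-stationary or
diffuse noise fields. Passing recovery tests on this data therefore
demonstrates the correctness and internal consistency of the chain —
not clinical-grade detector performance on hospital recordings.

## Numerical choices and study sizes

- Times are seconds from record start; sample indexing is 0-based;
  intervals are half-open `[start, end)`.
- All generators are deterministic given `seed`; independent stages
  draw from independent seeded streams.
- Recovery studies in the tests and the acceptance script use 15–30 s
  records (roughly 18–36 beats), which keeps the whole suite in the
  seconds range while leaving beat statistics meaningful; medians over
  that many beats are stable to well under the reported tolerances.
- The acceptance script reports the recovered parameters of the default
  noisy study (not a clean run), so its EMAT and INTERVAL carry the
  small biases described below.

## Known limitations

- The default ambient noise is a 50 Hz sinusoid, which lies inside the
  heart band and within 2 Hz of the S1 center frequency. The adaptive
  canceller therefore removes a sliver of genuine S1 energy along with
  the noise, shifting the S1 envelope peak and biasing EMAT low by
  about 2 ms (and INTERVAL by a similar margin) at 0 dB input SNR. This
  is a property of spectrally overlapping interference, not a bug; with
  white or babble-like noise the bias disappears.
- The Q-onset rule assumes a visible Q wave preceding R; QS complexes
  or heavy baseline wander would defeat the backward slope search.
- Breath segmentation assumes audible expiration quieter than
  inspiration; paradoxical or silent expiration yields merged phases.
- Streaming mode reproduces offline *causal* processing exactly;
  offline zero-phase results differ from streaming by the (intended)
  absence of group delay.
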