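"""Inspiration/expiration segmentation of the lung-sound envelope.

Inspiration is louder than expiration in adults; hysteresis thresholding
of the smoothed envelope finds the phases, and the louder phase of each
breath is labeled inspiration.
"""

import numpy as np

from cardiopatch import SynthConfig, envelope, generate_lung_sound, segment_breaths

cfg = SynthConfig(duration=60.0, breath_rate=12.0, insp_exp_amp_ratio=2.0, seed=5)
lung, truth = generate_lung_sound(cfg)
env = envelope(lung, method="rms", smooth_ms=100.0)
seg = segment_breaths(env)

print(f"truth: {len(truth.inspirations())} inspirations in {lung.duration:.0f} s "
      f"({cfg.breath_rate:.0f} breaths/min configured)")
print(f"detected: {len(seg.inspirations())} inspirations, {len(seg.expirations())} expirations")

fs = env.fs
def mean_env(intervals):
    return float(np.mean(np.concatenate(
        [env.samples[int(s * fs):int(e * fs)] for s, e in intervals])))

ratio = mean_env(seg.inspirations()) / mean_env(seg.expirations())
print(f"mean envelope, inspiration / expiration: {ratio:.2f} (configured amplitude ratio 2.0)")
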