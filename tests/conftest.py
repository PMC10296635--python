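import numpy as np
import pytest

from cardiopatch import (
    SynthConfig,
    generate_ecg,
    generate_heart_sound,
    generate_lung_sound,
)


@pytest.fixture(scope="session")
def clean_cfg():
    """Default study conditions, no beat jitter, no noise mixing needed."""
    return SynthConfig(duration=20.0, hrv_sd=0.0, seed=11)


@pytest.fixture(scope="session")
def clean_heart_fixture(clean_cfg):
    """ECG + heart sound with exact truth, generated once per session."""
    ecg, beats = generate_ecg(clean_cfg)
    heart, sound_truth = generate_heart_sound(beats, clean_cfg)
    return {"cfg": clean_cfg, "ecg": ecg, "beats": beats, "heart": heart, "truth": sound_truth}


@pytest.fixture(scope="session")
def lung_fixture():
    cfg = SynthConfig(duration=30.0, insp_exp_amp_ratio=2.0, breath_rate=15.0, seed=7)
    lung, truth = generate_lung_sound(cfg)
    return {"cfg": cfg, "lung": lung, "truth": truth}
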