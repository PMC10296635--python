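"""Derived parameters: detector accuracy against generator ground truth."""

import numpy as np
import pytest

from cardiopatch import (
    SynthConfig,
    TimeSeries,
    apply_filter,
    detect_q_onset,
    detect_r_peaks,
    detect_s1_s2,
    emat,
    envelope,
    generate_ecg,
    generate_heart_sound,
    generate_lung_sound,
    heart_band,
    heart_rate,
    s1_s2_interval,
    segment_breaths,
)
from cardiopatch.features import SeriesSummary
from cardiopatch.synth import BeatAnnotations

FS = 4000.0


def heart_envelope(heart_ts):
    return envelope(apply_filter(heart_ts, heart_band(fs=heart_ts.fs), zero_phase=True))


class TestEnvelope:
    def test_constant_signal_analytic_envelope_is_constant(self):
        ts = TimeSeries(np.full(4000, 2.5), FS)
        env = envelope(ts, method="analytic", smooth_ms=0.0)
        mid = env.samples[500:-500]
        assert np.allclose(mid, 2.5, rtol=1e-3)

    def test_pure_tone_envelope_is_its_amplitude(self):
        t = np.arange(int(2 * FS)) / FS
        ts = TimeSeries(np.sin(2 * np.pi * 48 * t), FS)
        env = envelope(ts, method="analytic", smooth_ms=0.0)
        mid = env.samples[int(0.2 * FS) : -int(0.2 * FS)]
        assert np.all((mid >= 0.95) & (mid <= 1.05))

    def test_analytic_magnitude_dominates_signal_magnitude(self):
        rng = np.random.default_rng(3)
        from scipy.signal import hilbert

        x = rng.standard_normal(2000)
        raw_env = np.abs(hilbert(x))
        assert np.all(raw_env >= np.abs(x) - 1e-9)

    def test_rms_method_on_tone_gives_rms_level(self):
        t = np.arange(int(2 * FS)) / FS
        ts = TimeSeries(np.sin(2 * np.pi * 100 * t), FS)
        env = envelope(ts, method="rms", smooth_ms=50.0)
        mid = env.samples[int(0.2 * FS) : -int(0.2 * FS)]
        assert np.allclose(mid, 1 / np.sqrt(2), rtol=0.05)

    def test_window_longer_than_signal_rejected(self):
        with pytest.raises(ValueError, match="longer"):
            envelope(TimeSeries(np.ones(10), FS), smooth_ms=1000.0)


class TestRPeaks:
    def test_clean_synth_recovers_every_beat_within_10ms(self, clean_heart_fixture):
        ecg, beats = clean_heart_fixture["ecg"], clean_heart_fixture["beats"]
        detected = detect_r_peaks(ecg)
        assert detected.size == len(beats)
        assert np.max(np.abs(detected - beats.r_peaks)) <= 0.010

    def test_flat_signal_yields_empty_with_warning(self):
        with pytest.warns(UserWarning):
            out = detect_r_peaks(TimeSeries(np.zeros(int(4 * FS)), FS))
        assert out.size == 0

    def test_noisy_ecg_matches_95pct_of_beats_within_20ms(self):
        matched = total = 0
        for seed in range(10):
            cfg = SynthConfig(duration=20.0, hrv_sd=0.005, seed=seed)
            ecg, beats = generate_ecg(cfg)
            rng = np.random.default_rng(1000 + seed)
            # additive white noise at 10 dB SNR
            p_sig = np.mean(ecg.samples**2)
            noise = rng.standard_normal(len(ecg)) * np.sqrt(p_sig / 10.0)
            noisy = ecg.copy_with(ecg.samples + noise)
            detected = detect_r_peaks(noisy)
            for r in beats.r_peaks:
                total += 1
                if detected.size and np.min(np.abs(detected - r)) <= 0.020:
                    matched += 1
        assert matched / total >= 0.95


class TestQOnset:
    def test_clean_synth_onsets_within_5ms_of_truth(self, clean_heart_fixture):
        ecg, beats = clean_heart_fixture["ecg"], clean_heart_fixture["beats"]
        est = detect_q_onset(ecg, detect_r_peaks(ecg))
        assert len(est) == len(beats)
        assert np.max(np.abs(est.q_onsets - beats.q_onsets)) <= 0.005

    def test_q_onset_always_precedes_r_peak(self, clean_heart_fixture):
        ecg = clean_heart_fixture["ecg"]
        est = detect_q_onset(ecg, detect_r_peaks(ecg))
        assert np.all(est.q_onsets < est.r_peaks)

    def test_beat_too_close_to_record_start_is_dropped(self, clean_heart_fixture):
        ecg, beats = clean_heart_fixture["ecg"], clean_heart_fixture["beats"]
        real_r = beats.r_peaks[3]
        with pytest.warns(UserWarning, match="record start"):
            est = detect_q_onset(ecg, np.array([0.05, real_r]))
        assert est.r_peaks.size == 1 and est.r_peaks[0] == real_r


class TestHeartRate:
    def test_constant_rr_833ms_gives_72_bpm(self):
        r = np.arange(10) * (50.0 / 60.0) + 1.0
        beats = BeatAnnotations(q_onsets=r - 0.07, r_peaks=r)
        assert heart_rate(beats).summary == pytest.approx(72.0)

    def test_constant_rr_1s_gives_60_bpm(self):
        r = np.arange(10) * 1.0 + 1.0
        beats = BeatAnnotations(q_onsets=r - 0.07, r_peaks=r)
        assert heart_rate(beats).summary == pytest.approx(60.0)

    def test_fewer_than_two_beats_rejected(self):
        beats = BeatAnnotations(q_onsets=np.array([0.93]), r_peaks=np.array([1.0]))
        with pytest.raises(ValueError, match="insufficient beats"):
            heart_rate(beats)

    def test_jittered_72bpm_recovered_within_1bpm(self):
        cfg = SynthConfig(duration=60.0, hr_bpm=72.0, hrv_sd=0.005, seed=2)
        ecg, _ = generate_ecg(cfg)
        beats = detect_q_onset(ecg, detect_r_peaks(ecg))
        assert heart_rate(beats, window_s=None).summary == pytest.approx(72.0, abs=1.0)


class TestS1S2:
    def test_emat_recovered_within_2_5ms_per_beat(self, clean_heart_fixture):
        ecg, heart = clean_heart_fixture["ecg"], clean_heart_fixture["heart"]
        beats_est = detect_q_onset(ecg, detect_r_peaks(ecg))
        sounds = detect_s1_s2(heart_envelope(heart), beats_est)
        per_beat = (sounds.s1_time - beats_est.q_onsets[sounds.beat_index]) * 1000
        assert np.max(np.abs(per_beat - 76.0)) <= 2.5

    def test_silent_s2_flagged_low_confidence(self):
        cfg = SynthConfig(duration=15.0, hrv_sd=0.0, s2_amp=0.0, seed=4)
        ecg, beats = generate_ecg(cfg)
        heart, _ = generate_heart_sound(beats, cfg)
        sounds = detect_s1_s2(heart_envelope(heart), beats)
        assert len(sounds) > 0
        assert np.all(sounds.s2_low_confidence)
        assert not np.any(sounds.s1_low_confidence)

    def test_intensities_scale_linearly_with_amplitude(self, clean_heart_fixture):
        heart, beats = clean_heart_fixture["heart"], clean_heart_fixture["beats"]
        s1 = detect_s1_s2(heart_envelope(heart), beats)
        s2 = detect_s1_s2(heart_envelope(heart.copy_with(2.0 * heart.samples)), beats)
        np.testing.assert_allclose(s2.s1_intensity, 2.0 * s1.s1_intensity, rtol=1e-9)
        np.testing.assert_allclose(s2.s2_intensity, 2.0 * s1.s2_intensity, rtol=1e-9)

    def test_timing_invariant_to_amplitude_scale(self, clean_heart_fixture):
        heart, beats = clean_heart_fixture["heart"], clean_heart_fixture["beats"]
        a = detect_s1_s2(heart_envelope(heart), beats)
        b = detect_s1_s2(heart_envelope(heart.copy_with(7.3 * heart.samples)), beats)
        np.testing.assert_array_equal(a.s1_time, b.s1_time)
        np.testing.assert_array_equal(a.s2_time, b.s2_time)


class TestIntervalAndEmat:
    def test_truth_fed_emat_is_exact(self):
        r = np.arange(5) * 0.8 + 1.0
        beats = BeatAnnotations(q_onsets=r - 0.07, r_peaks=r)
        from cardiopatch.features import SoundAnnotations

        sounds = SoundAnnotations(
            beat_index=np.arange(5),
            s1_time=beats.q_onsets + 0.076,
            s2_time=beats.q_onsets + 0.076 + 0.30,
            s1_intensity=np.ones(5),
            s2_intensity=np.ones(5),
            s1_low_confidence=np.zeros(5, bool),
            s2_low_confidence=np.zeros(5, bool),
        )
        assert emat(beats, sounds).summary == pytest.approx(76.0)
        assert s1_s2_interval(sounds).summary == pytest.approx(300.0)

    def test_s1_at_q_onset_gives_zero_emat(self):
        r = np.array([1.0, 2.0])
        beats = BeatAnnotations(q_onsets=r - 0.07, r_peaks=r)
        from cardiopatch.features import SoundAnnotations

        sounds = SoundAnnotations(
            beat_index=np.arange(2),
            s1_time=beats.q_onsets,
            s2_time=beats.q_onsets + 0.3,
            s1_intensity=np.ones(2),
            s2_intensity=np.ones(2),
            s1_low_confidence=np.zeros(2, bool),
            s2_low_confidence=np.zeros(2, bool),
        )
        assert emat(beats, sounds).summary == pytest.approx(0.0)

    @pytest.mark.parametrize("emat_s,interval_s", [(0.060, 0.250), (0.076, 0.300), (0.100, 0.350)])
    def test_pipeline_recovery_sweep(self, emat_s, interval_s):
        cfg = SynthConfig(duration=15.0, hrv_sd=0.0, emat=emat_s, s1_s2_interval=interval_s, seed=6)
        ecg, beats = generate_ecg(cfg)
        heart, _ = generate_heart_sound(beats, cfg)
        beats_est = detect_q_onset(ecg, detect_r_peaks(ecg))
        sounds = detect_s1_s2(heart_envelope(heart), beats_est)
        assert emat(beats_est, sounds).summary == pytest.approx(emat_s * 1000, abs=2.5)
        assert s1_s2_interval(sounds).summary == pytest.approx(interval_s * 1000, abs=5.0)

    def test_single_beat_summary_is_that_value(self):
        from cardiopatch.features import SoundAnnotations

        sounds = SoundAnnotations(
            beat_index=np.array([0]),
            s1_time=np.array([1.0]),
            s2_time=np.array([1.31]),
            s1_intensity=np.array([1.0]),
            s2_intensity=np.array([0.5]),
            s1_low_confidence=np.array([False]),
            s2_low_confidence=np.array([False]),
        )
        assert s1_s2_interval(sounds).summary == pytest.approx(310.0)


class TestSegmentBreaths:
    def test_detected_inspiration_count_matches_truth(self, lung_fixture):
        lung, truth = lung_fixture["lung"], lung_fixture["truth"]
        env = envelope(lung, method="rms", smooth_ms=100.0)
        seg = segment_breaths(env)
        assert len(seg.inspirations()) == len(truth.inspirations())

    def test_inspirations_louder_than_expirations(self, lung_fixture):
        lung = lung_fixture["lung"]
        env = envelope(lung, method="rms", smooth_ms=100.0)
        seg = segment_breaths(env)
        fs = env.fs

        def mean_env(intervals):
            return np.mean(np.concatenate(
                [env.samples[int(s * fs) : int(e * fs)] for s, e in intervals]))

        assert mean_env(seg.inspirations()) > mean_env(seg.expirations())

    def test_constant_amplitude_noise_yields_empty(self):
        rng = np.random.default_rng(8)
        flat = TimeSeries(np.abs(rng.standard_normal(int(10 * FS))) + 5.0, FS)
        with pytest.warns(UserWarning, match="no excursions"):
            seg = segment_breaths(flat)
        assert len(seg) == 0
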