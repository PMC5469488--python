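"""Syllable-detection pipeline: RMS gate, spectrogram, template correlation,
the streaming detector against an independently coded offline full scan."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from looplab.daf import (
    DAFConfig,
    DAFDetector,
    detect_stream,
    rms,
    score_detections,
    spectrogram_20ms,
    template_corr,
    template_from_clip,
)
from looplab.errors import ValidationError
from looplab.fixtures import SyntheticSongSpec, make_song, render_syllable


# ---------------------------------------------------------------------------
# Offline oracle: full-scan re-implementation of the published rules
# ---------------------------------------------------------------------------


def offline_detections(x, config, template, feedback_len=0):
    """Independent pass over the whole recording: for every evaluation
    instant compute the trailing RMS and (in triggered mode) the trailing
    spectrogram correlation, replaying the idle/triggered automaton."""
    step = config.eval_interval
    nrms = config.rms_samples
    nspec = config.spec_samples
    win = config.stft_window
    hop = config.stft_hop
    taper = np.hanning(win + 1)[:-1]  # periodic Hann, as in an STFT
    freqs = np.fft.rfftfreq(win, 1.0 / config.rate)
    rows = (freqs >= config.band[0]) & (freqs <= config.band[1])
    tvec = template.ravel()
    tvec = tvec - tvec.mean()
    tnorm = np.sqrt((tvec**2).sum())

    def corr_at(n_end):
        seg = x[n_end - nspec:n_end]
        n_frames = 1 + (nspec - win) // hop
        mats = []
        for f in range(n_frames):
            fr = seg[f * hop:f * hop + win] * taper
            mats.append(np.abs(np.fft.rfft(fr))[rows])
        v = np.column_stack(mats).ravel()
        v = v - v.mean()
        denom = np.sqrt((v**2).sum()) * tnorm
        return 0.0 if denom == 0 else float(v @ tvec) / denom

    mode = "idle"
    last_det = -np.inf
    refractory = feedback_len / config.rate if feedback_len else 0.1
    playing_until = -1.0
    out = []
    for n in range(step, len(x) + 1, step):
        if n < nrms:
            continue
        t = n / config.rate
        level = float(np.sqrt(np.mean(x[n - nrms:n] ** 2)))
        if mode == "idle":
            if level > config.rms_threshold:
                mode = "triggered"
        else:
            if n >= nspec:
                r = corr_at(n)
                if r > config.corr_threshold and t - last_det >= refractory:
                    out.append(t)
                    last_det = t
                    if feedback_len:
                        playing_until = t + feedback_len / config.rate
            if level < config.rms_threshold and t >= playing_until:
                mode = "idle"
    return np.asarray(out)


def song_and_template(seed=3, n_motifs=10, noise=0.001):
    spec = SyntheticSongSpec(n_motifs=n_motifs, noise_floor=noise, seed=seed)
    wave, events = make_song(spec)
    cfg = DAFConfig()
    clip = render_syllable(spec.syllables[spec.target], spec.rate)
    return wave, events, cfg, template_from_clip(clip, cfg)


# ---------------------------------------------------------------------------
# Primitive operations
# ---------------------------------------------------------------------------


class TestRMS:
    def test_constant_signal(self):
        assert rms(np.full(300, 2.0)) == pytest.approx(2.0)

    def test_sine_over_whole_cycles_is_a_over_sqrt2(self):
        t = np.arange(300) / 30_000.0  # exactly 10 cycles of 1 kHz
        assert rms(0.8 * np.sin(2 * np.pi * 1000 * t)) == pytest.approx(
            0.8 / np.sqrt(2), rel=1e-9
        )

    def test_zeros_and_empty(self):
        assert rms(np.zeros(10)) == 0.0
        with pytest.raises(ValidationError):
            rms(np.empty(0))

    @given(st.lists(st.floats(min_value=-10, max_value=10), min_size=1, max_size=50))
    def test_sign_flip_invariant(self, vals):
        x = np.asarray(vals)
        assert rms(-x) == rms(x)


class TestSpectrogram:
    def test_pure_tone_peaks_in_the_right_bin(self):
        cfg = DAFConfig()
        t = np.arange(cfg.spec_samples) / cfg.rate
        spec = spectrogram_20ms(np.sin(2 * np.pi * 3000.0 * t), cfg)
        freqs = np.fft.rfftfreq(cfg.stft_window, 1 / cfg.rate)
        band = freqs[(freqs >= cfg.band[0]) & (freqs <= cfg.band[1])]
        peak_rows = spec.argmax(axis=0)
        expected = np.abs(band - 3000.0).argmin()
        assert np.all(peak_rows == expected)

    def test_zeros_and_linearity(self):
        cfg = DAFConfig()
        z = spectrogram_20ms(np.zeros(cfg.spec_samples), cfg)
        assert np.all(z == 0.0)
        x = np.random.default_rng(0).standard_normal(cfg.spec_samples)
        assert np.allclose(spectrogram_20ms(2 * x, cfg), 2 * spectrogram_20ms(x, cfg))

    def test_wrong_length_rejected(self):
        with pytest.raises(ValidationError):
            spectrogram_20ms(np.zeros(100), DAFConfig())


class TestTemplateCorr:
    def test_self_and_negation(self):
        rng = np.random.default_rng(1)
        a = rng.random((40, 8))
        assert template_corr(a, a) == pytest.approx(1.0)
        assert template_corr(2 * a.mean() - a, a) == pytest.approx(-1.0)

    def test_zero_variance_defined_as_zero(self):
        a = np.random.default_rng(2).random((40, 8))
        assert template_corr(np.full_like(a, 3.0), a) == 0.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            template_corr(np.zeros((4, 4)), np.zeros((4, 5)))

    def test_independent_noise_correlates_weakly(self):
        """Monte-Carlo null: |r| between independent white-noise
        spectrograms stays below 0.5 at this matrix size."""
        cfg = DAFConfig()
        rng = np.random.default_rng(7)
        rs = []
        for _ in range(50):
            a = spectrogram_20ms(rng.standard_normal(cfg.spec_samples), cfg)
            b = spectrogram_20ms(rng.standard_normal(cfg.spec_samples), cfg)
            rs.append(abs(template_corr(a, b)))
        assert max(rs) < 0.5


# ---------------------------------------------------------------------------
# Streaming detector
# ---------------------------------------------------------------------------


class TestDetector:
    def test_silence_stays_idle(self):
        _, _, cfg, tmpl = song_and_template()
        det = DAFDetector(cfg, tmpl)
        for _ in range(3000):
            detected, fb = det.step(0.0)
            assert not detected and fb == 0.0
        assert det.mode == "idle"
        assert det.detections == []

    def test_streaming_equals_offline_full_scan(self):
        wave, _, cfg, tmpl = song_and_template(seed=5, n_motifs=8)
        online, _ = detect_stream(wave, cfg, tmpl)
        offline = offline_detections(wave, cfg, tmpl)
        assert np.allclose(online, offline)

    def test_clean_song_hit_rate_one_no_false_positives(self):
        wave, events, cfg, tmpl = song_and_template(seed=4)
        online, _ = detect_stream(wave, cfg, tmpl)
        truth = [e["offset"] for e in events if e["is_target"]]
        hit, fp, _ = score_detections(online, truth, 0.025)
        assert hit == 1.0
        assert fp == 0

    def test_detection_within_20ms_of_syllable_completion(self):
        wave, events, cfg, tmpl = song_and_template(seed=6, n_motifs=5)
        online, _ = detect_stream(wave, cfg, tmpl)
        offsets = np.array([e["offset"] for e in events if e["is_target"]])
        assert len(online) == len(offsets)
        assert np.all(np.abs(online - offsets) <= 0.020 + 1e-9)

    def test_feedback_played_once_with_refractory(self):
        wave, events, cfg, tmpl = song_and_template(seed=8, n_motifs=4)
        # 100 ms feedback ⇒ 100 ms implied refractory, covering the
        # syllable's remaining high-correlation instants
        feedback = 0.3 * np.sin(2 * np.pi * 2000 * np.arange(3000) / cfg.rate)
        online, fb_out = detect_stream(wave, cfg, tmpl, feedback)
        n_targets = sum(e["is_target"] for e in events)
        assert len(online) == n_targets
        # each detection plays the waveform exactly once
        assert np.count_nonzero(fb_out) == n_targets * np.count_nonzero(feedback)


class TestScoring:
    def test_perfect_and_empty(self):
        assert score_detections([1.0, 2.0], [1.0, 2.0], 0.01)[:2] == (1.0, 0)
        assert score_detections([], [1.0, 2.0], 0.01)[:2] == (0.0, 0)

    def test_spurious_detection_is_a_false_positive(self):
        hit, fp, _ = score_detections([1.0, 5.0], [1.0], 0.01)
        assert hit == 1.0 and fp == 1

    def test_one_to_one_matching(self):
        # two detections near one truth event: only one may match
        hit, fp, m = score_detections([1.0, 1.005], [1.0], 0.01)
        assert hit == 1.0 and fp == 1 and len(m) == 1
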