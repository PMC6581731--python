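"""Framing, Hanning window, Welch PSD, band power, and PCC features."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from saelstm import features as feat


def brute_force_frame_count(T, W, S):
    count = 0
    start = 0
    while start + W <= T:
        count += 1
        start += S
    return count


class TestFraming:
    def test_deap_trial_gives_125_frames(self):
        x = np.zeros(8064)
        frames = feat.frame_signal(x, 128, feat.FrameSpec(1.0, 0.5))
        assert frames.shape == (125, 128)

    @pytest.mark.parametrize("dur_s,expected", [(1.0, 1), (2.0, 3)])
    def test_short_signals(self, dur_s, expected):
        x = np.arange(int(dur_s * 128), dtype=float)
        frames = feat.frame_signal(x, 128, feat.FrameSpec(1.0, 0.5))
        assert frames.shape[0] == expected
        np.testing.assert_array_equal(frames[0], x[:128])

    def test_signal_shorter_than_window_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            feat.frame_signal(np.zeros(100), 128, feat.FrameSpec(1.0, 0.5))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(T=st.integers(16, 2000), W=st.integers(2, 300), S=st.integers(1, 300))
    def test_frame_count_matches_enumeration(self, T, W, S):
        if S > W or W > T:
            return
        spec = feat.FrameSpec(window_s=W, step_s=S)  # fs=1 => samples
        frames = feat.frame_signal(np.zeros(T), 1.0, spec)
        assert frames.shape[0] == brute_force_frame_count(T, W, S)
        assert frames.shape[0] == spec.n_frames(T, 1.0)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            feat.FrameSpec(window_s=1.0, step_s=0.0)
        with pytest.raises(ValueError):
            feat.FrameSpec(window_s=1.0, step_s=2.0)


class TestHanning:
    def test_closed_form_values(self):
        w = feat.hanning(4)
        np.testing.assert_allclose(w, [0.0, 0.75, 0.75, 0.0])

    def test_endpoints_zero_and_odd_midpoint_one(self):
        w = feat.hanning(129)
        assert w[0] == 0.0 and w[-1] == 0.0
        assert w[64] == pytest.approx(1.0)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            feat.hanning(1)


class TestWelchPSD:
    def test_pure_tone_localized(self):
        t = np.arange(128) / 128.0
        x = np.sin(2 * np.pi * 10 * t)
        freqs, psd = feat.welch_psd(x, 128)
        assert freqs[np.argmax(psd)] == pytest.approx(10.0)
        assert freqs[1] - freqs[0] == pytest.approx(1.0)  # 1 Hz resolution

    def test_zero_frame_gives_zero_psd(self):
        _, psd = feat.welch_psd(np.zeros(128), 128)
        assert np.all(psd == 0)

    def test_parseval_white_noise(self, rng):
        """The PSD integral approximates the sample variance (Parseval)."""
        x = rng.standard_normal(4096)
        freqs, psd = feat.welch_psd(x, 128)
        power = np.trapezoid(psd, freqs)
        assert power == pytest.approx(x.var(), rel=0.05)


class TestBandPower:
    @pytest.mark.parametrize("f0,band", [(10.0, "alpha"), (40.0, "gamma")])
    def test_tone_lands_in_its_band(self, f0, band):
        t = np.arange(8064) / 128.0
        x = np.sin(2 * np.pi * f0 * t)
        freqs, psd = feat.welch_psd(x, 128)
        bp = feat.band_power(freqs, psd, feat.EEG_BANDS[band])
        total = feat.band_power(freqs, psd, (4, 45))
        assert bp / total >= 0.95

    def test_zero_signal_zero_power_every_band(self):
        freqs, psd = feat.welch_psd(np.zeros(128), 128)
        for band in feat.EEG_BANDS.values():
            assert feat.band_power(freqs, psd, band) == 0.0

    def test_band_beyond_nyquist_rejected(self):
        freqs, psd = feat.welch_psd(np.zeros(128), 128)
        with pytest.raises(ValueError):
            feat.band_power(freqs, psd, (70, 80))

    def test_band_sum_below_total_power(self, rng):
        """Across the five full bands the summed power cannot exceed the
        total signal power (windowing loss aside)."""
        x = rng.standard_normal(8064)
        freqs, psd = feat.welch_psd(x, 128)
        total = np.trapezoid(psd, freqs)
        band_sum = sum(feat.band_power(freqs, psd, b) for b in feat.EEG_BANDS.values())
        assert band_sum <= total * 1.02


class TestPCC:
    def test_self_and_anti_correlation(self, rng):
        x = rng.standard_normal(50)
        assert feat.pcc(x, x) == pytest.approx(1.0)
        assert feat.pcc(x, -x) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        assert feat.pcc([1, 2, 3], [1, 2, 4]) == pytest.approx(0.9820, abs=5e-5)

    def test_matches_reference_implementation(self, rng):
        x, y = rng.standard_normal((2, 200))
        assert feat.pcc(x, y) == pytest.approx(stats.pearsonr(x, y)[0], abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(feat.UndefinedMetricError):
            feat.pcc(np.ones(10), np.arange(10))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(a=st.floats(-5, 5), b=st.floats(-5, 5), seed=st.integers(0, 100))
    def test_scale_shift_invariance(self, a, b, seed):
        if abs(a) < 1e-3:
            return
        r = np.random.default_rng(seed).standard_normal((2, 30))
        base = feat.pcc(r[0], r[1])
        assert feat.pcc(a * r[0] + b, r[1]) == pytest.approx(np.sign(a) * base, abs=1e-9)
        assert feat.pcc(r[1], r[0]) == pytest.approx(base, abs=1e-12)


class TestFeatureSequences:
    def test_fbp_sequence_shape_and_names(self):
        trial = np.random.default_rng(1).standard_normal((1, 12, 8064))
        seqs = feat.extract_fbp_sequence(trial, 128)
        assert seqs[0].values.shape == (125, 48)
        assert seqs[0].feature_names[:4] == [
            "ch0:theta", "ch0:alpha", "ch0:beta", "ch0:gamma"]
        assert seqs[0].feature_names[4] == "ch1:theta"  # channel-major order

    def test_single_band_source_dominates_its_column(self):
        from saelstm import synth
        panel = synth.simulate_sources(
            1, 2, 4, 128, seed=5,
            band_profile=[[("alpha", 1.0)], [("gamma", 1.0)]], pink_noise_rel=0.0,
        )
        seqs = feat.extract_fbp_sequence(panel.sources, 128)
        v = seqs[0].values  # (frames, 2*4)
        assert (v[:, 1].sum() / v[:, :4].sum()) >= 0.9  # ch0 alpha
        assert (v[:, 7].sum() / v[:, 4:].sum()) >= 0.9  # ch1 gamma

    def test_zero_trial_gives_zero_sequence(self):
        seqs = feat.extract_fbp_sequence(np.zeros((1, 3, 256)), 128)
        assert np.all(seqs[0].values == 0)

    def test_pcc_sequence_width_and_identical_channels(self):
        x = np.tile(np.random.default_rng(2).standard_normal(256), (12, 1))[None]
        seqs = feat.extract_pcc_sequence(x, 128)
        assert seqs[0].values.shape[1] == 11
        np.testing.assert_allclose(seqs[0].values, 1.0)

    def test_orthogonal_reference_gives_near_zero(self):
        t = np.arange(256) / 128.0
        ref = np.sin(2 * np.pi * 8 * t)
        others = [np.cos(2 * np.pi * 8 * t), np.sin(2 * np.pi * 16 * t)]
        x = np.stack([ref] + others)[None]
        seqs = feat.extract_pcc_sequence(x, 128)
        assert np.all(np.abs(seqs[0].values) < 0.1)

    def test_constant_channel_flagged_as_zero(self):
        x = np.random.default_rng(3).standard_normal((1, 3, 256))
        x[0, 2] = 7.0  # constant channel
        seqs = feat.extract_pcc_sequence(x, 128)
        assert np.all(seqs[0].values[:, 1] == 0.0)

    def test_pairwise_mode_width(self):
        x = np.random.default_rng(4).standard_normal((1, 12, 256))
        seqs = feat.extract_pcc_sequence(x, 128, pairwise=True)
        assert seqs[0].values.shape[1] == 66
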