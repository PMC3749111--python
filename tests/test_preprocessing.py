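"""Preprocessing chain: CAR, filter bank, envelope, decimation, z-scoring."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from ecogarm import PipelineConfig, RawSession
from ecogarm.preprocessing import (
    band_envelopes,
    bandpass_filterbank,
    bandpass_gain,
    common_average_reference,
    downsample,
    envelope,
    preprocess,
    zscore_normalize,
)

FS = 1000.0
BANDS = PipelineConfig().band_edges


def steady_amplitude(y, fs=FS):
    """Peak amplitude of the last second (after transient decay)."""
    tail = y[int(-fs):]
    return float(np.max(np.abs(tail)))


class TestCommonAverageReference:
    def test_two_channel_example(self):
        out = common_average_reference(np.array([[1.0, 3.0]]))
        assert np.allclose(out, [[-1.0, 1.0]])

    def test_matches_brute_force_row_means(self, rng):
        x = rng.standard_normal((5, 4))
        expect = np.array([[v - row.mean() for v in row] for row in x])
        assert np.allclose(common_average_reference(x), expect, atol=1e-15)

    @given(arrays(float, (7, 3), elements=st.floats(-1e6, 1e6)))
    @settings(deadline=None, max_examples=25, derandomize=True)
    def test_row_sums_vanish(self, x):
        out = common_average_reference(x)
        assert np.all(np.abs(out.sum(axis=1)) <= 1e-9 * max(1.0, np.abs(x).max()))
        assert out.shape == x.shape

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError):
            common_average_reference(np.ones((10, 1)))


class TestFilterbank:
    def test_passband_tone_passes(self):
        t = np.arange(int(5 * FS)) / FS
        x = np.sin(2 * np.pi * 25.0 * t)[:, None]
        out = bandpass_filterbank(x, BANDS, 4, FS)
        beta2 = out[:, 4]  # 20-30 Hz band of channel 0
        assert abs(steady_amplitude(beta2) - 1.0) < 0.05

    def test_stopband_tone_blocked(self):
        t = np.arange(int(5 * FS)) / FS
        x = np.sin(2 * np.pi * 25.0 * t)[:, None]
        out = bandpass_filterbank(x, BANDS, 4, FS)
        delta = out[:, 0]
        assert steady_amplitude(delta) < 0.01

    def test_zero_in_zero_out(self):
        out = bandpass_filterbank(np.zeros((500, 2)), BANDS, 4, FS)
        assert out.shape == (500, 14)
        assert np.all(out == 0)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            bandpass_filterbank(np.zeros((100, 1)), ((50.0, 600.0),), 4, FS)

    @pytest.mark.parametrize("band", BANDS, ids=[f"{lo}-{hi}" for lo, hi in BANDS])
    def test_gain_matches_analytic_response_at_center(self, band):
        lo, hi = band
        f0 = 0.5 * (lo + hi)
        t = np.arange(int(8 * FS)) / FS
        x = np.sin(2 * np.pi * f0 * t)[:, None]
        out = bandpass_filterbank(x, (band,), 4, FS)
        expect = bandpass_gain(band, 4, f0)
        assert abs(steady_amplitude(out[:, 0]) - expect) < 0.05 * max(expect, 1e-3)


class TestEnvelope:
    def test_negative_constant_settles_to_magnitude(self):
        x = np.full(int(5 * FS), -0.7)
        out = envelope(x, 2.2, 2, FS)
        assert abs(out[-1] - 0.7) < 1e-3

    def test_sinusoid_settles_to_rectified_mean(self):
        t = np.arange(int(6 * FS)) / FS
        x = np.sin(2 * np.pi * 40.0 * t)
        out = envelope(x, 2.2, 2, FS)
        assert abs(np.mean(out[int(-FS):]) - 2 / np.pi) < 0.1 * 2 / np.pi

    def test_zero_in_zero_out(self):
        assert np.all(envelope(np.zeros(100), 2.2, 2, FS) == 0)


class TestDownsample:
    def test_keeps_every_kth_from_zero(self):
        ramp = np.arange(1000.0)
        out = downsample(ramp, 1000.0, 100.0)
        assert np.array_equal(out, np.arange(0.0, 1000.0, 10.0))

    def test_length_contract(self):
        assert downsample(np.zeros(2000), 1000.0, 100.0).shape[0] == 200

    def test_non_integer_ratio_rejected(self):
        with pytest.raises(ValueError):
            downsample(np.zeros(100), 1000.0, 300.0)


class TestZScore:
    def test_hand_computed_example(self):
        z, mu, sigma, keep = zscore_normalize(np.array([1.0, 2.0, 3.0])[:, None])
        assert np.allclose(z.ravel(), [-1.224745, 0.0, 1.224745], atol=1e-6)
        assert np.isclose(sigma[0], 0.816497, atol=1e-6)  # population form

    def test_constant_feature_dropped_with_warning(self, caplog):
        x = np.column_stack([np.arange(5.0), np.ones(5)])
        z, mu, sigma, keep = zscore_normalize(x)
        assert keep.tolist() == [True, False]
        assert z.shape == (5, 1)
        with pytest.raises(ValueError):
            zscore_normalize(x, strict=True)

    def test_window_statistics_reused_on_held_out_rows(self, rng):
        x = rng.standard_normal((100, 3)) * 5 + 2
        window = np.arange(60)
        z, mu, sigma, keep = zscore_normalize(x, window)
        assert np.allclose(z[window].mean(axis=0), 0, atol=1e-9)
        assert np.allclose(z[window].std(axis=0), 1, atol=1e-9)
        z2, *_ = zscore_normalize(x, mu=mu, sigma=sigma)
        assert np.allclose(z2, z, atol=1e-12)


class TestPreprocessChain:
    def test_feature_count_is_channels_times_bands(self, rng):
        sig = rng.standard_normal((3000, 15))
        session = RawSession(signal=sig, fs_signal=FS)
        feats = preprocess(session, PipelineConfig())
        assert feats.n_features == 15 * 7
        assert feats.fs == 100.0

    def test_chain_is_deterministic(self, rng):
        sig = rng.standard_normal((2000, 3))
        session = RawSession(signal=sig, fs_signal=FS)
        cfg = PipelineConfig()
        a = preprocess(session, cfg).envelopes
        b = preprocess(session, cfg).envelopes
        assert np.array_equal(a, b)

    def test_modulated_pair_has_highest_correlation_with_modulator(self, rng):
        # channel 2, gamma2 carrier amplitude-modulated by a slow signal;
        # every other (channel, band) carries unmodulated noise.
        n_s, n_ch = 30_000, 4
        t = np.arange(n_s) / FS
        slow = 1.0 + 0.5 * np.sin(2 * np.pi * 0.3 * t)
        sig = 0.05 * rng.standard_normal((n_s, n_ch))
        sig[:, 2] += np.sin(2 * np.pi * 70.0 * t) * slow
        sig[:, 0] += np.sin(2 * np.pi * 10.0 * t)
        session = RawSession(signal=sig, fs_signal=FS)
        feats = preprocess(session, PipelineConfig())
        slow_lo = slow[::10]
        cc = [abs(np.corrcoef(feats.envelopes[:, j], slow_lo)[0, 1])
              for j in range(feats.n_features)]
        assert int(np.argmax(cc)) == 2 * 7 + 6  # (channel 2, gamma2)

    def test_zero_phase_mode_differs_but_same_shape(self, rng):
        sig = rng.standard_normal((2000, 2))
        session = RawSession(signal=sig, fs_signal=FS)
        causal = band_envelopes(session, PipelineConfig())
        zp = band_envelopes(session, PipelineConfig(filter_mode="zero_phase"))
        assert causal.shape == zp.shape
        assert not np.allclose(causal, zp)
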