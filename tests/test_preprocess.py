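"""Preprocessing chain: filter response, noise estimate, detection,
extraction and gradient features."""
import numpy as np
import pytest

from pseudosorter import simulate
from pseudosorter.preprocess import (DetectionConfig, WaveformSet,
                                     bandpass_filter, detect_spikes,
                                     estimate_noise, extract_waveforms,
                                     minmax_normalize, normalize_and_gradient,
                                     preprocess_trace)

FS = 20_000.0


class TestBandpass:
    def test_dc_rejected(self):
        x = np.full(4000, 5.0)
        out = bandpass_filter(x, DetectionConfig(), FS)
        assert np.max(np.abs(out[500:-500])) < 5e-6

    def test_passband_gain(self):
        t = np.arange(40000) / FS
        x = np.sin(2 * np.pi * 1000.0 * t)
        out = bandpass_filter(x, DetectionConfig(), FS)
        amp = np.max(np.abs(out[5000:-5000]))
        assert 0.9 <= amp <= 1.0 + 1e-9

    def test_stopband_attenuation(self):
        t = np.arange(40000) / FS
        x = np.sin(2 * np.pi * 10.0 * t)
        out = bandpass_filter(x, DetectionConfig(), FS)
        assert np.max(np.abs(out[5000:-5000])) < 0.1

    def test_invalid_band_raises(self):
        with pytest.raises(ValueError):
            bandpass_filter(np.zeros(1000),
                            DetectionConfig(band_high_hz=15000.0), FS)


class TestEstimateNoise:
    def test_constant_and_zero(self):
        assert estimate_noise(np.full(100, 2.0)) == pytest.approx(2 / 0.6745)
        assert estimate_noise(np.zeros(100)) == 0.0

    def test_standard_normal_calibration(self):
        x = np.random.default_rng(0).standard_normal(10 ** 6)
        assert estimate_noise(x) == pytest.approx(1.0, abs=0.01)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            estimate_noise(np.array([]))


class TestDetect:
    def _noise(self, n=20000, seed=0):
        return np.random.default_rng(seed).standard_normal(n)

    def test_subthreshold_trace_yields_nothing(self):
        x = self._noise()
        x = x / np.max(np.abs(x)) * 4.0  # max |x| < 5 sigma_m-ish
        events = detect_spikes(x, DetectionConfig(), sigma_m=1.0)
        assert events.size == 0

    def test_single_deflection_found(self):
        x = self._noise()
        x[1000:1004] -= 10.0
        events = detect_spikes(x, DetectionConfig(), sigma_m=1.0)
        assert events.size == 1
        assert abs(events[0] - 1000) <= 2

    def test_dead_time_merges_close_events(self):
        x = np.zeros(2000)
        x[500] = x[505] = -10.0
        cfg = DetectionConfig(dead_time_samples=40)
        events = detect_spikes(x, cfg, sigma_m=1.0)
        assert events.size == 1

    def test_edge_events_dropped(self):
        x = np.zeros(2000)
        x[10] = x[1995] = -10.0
        events = detect_spikes(x, DetectionConfig(), sigma_m=1.0)
        assert events.size == 0


class TestExtract:
    def test_window_definition(self):
        x = np.random.default_rng(1).standard_normal(5000)
        cfg = DetectionConfig(align_on="threshold_crossing")
        wset = extract_waveforms(x, np.array([1000]), cfg, FS)
        np.testing.assert_array_equal(wset.waveforms[0], x[980:1044])
        assert wset.times_ms[0] == pytest.approx(1000 / FS * 1e3)

    def test_minimum_alignment_recenters(self):
        x = np.zeros(5000)
        x[1003] = -5.0  # trough lags the crossing by 3 samples
        wset = extract_waveforms(x, np.array([1000]),
                                 DetectionConfig(align_on="minimum"), FS)
        assert int(np.argmin(wset.waveforms[0])) == 20

    def test_edge_event_dropped(self):
        x = np.zeros(1000)
        wset = extract_waveforms(x, np.array([10, 500]),
                                 DetectionConfig(), FS)
        assert len(wset) == 1


class TestNormalizeAndGradient:
    def _wset(self, rows):
        rows = np.atleast_2d(rows)
        return WaveformSet(waveforms=rows,
                           times_ms=np.arange(rows.shape[0], dtype=float),
                           dt_s=5e-5)

    def test_linear_ramp_hand_computed(self):
        out = normalize_and_gradient(self._wset(np.arange(64.0)))
        assert out.features.shape == (1, 63)
        np.testing.assert_allclose(out.features[0], (1 / 63) / 5e-5,
                                   rtol=1e-12)

    def test_flat_row_zeroed_and_flagged(self):
        out = normalize_and_gradient(self._wset(np.full(64, 3.0)))
        np.testing.assert_array_equal(out.features[0], np.zeros(63))
        assert out.flat_mask[0]

    def test_feature_width_is_63(self, two_class_set):
        wset, _ = two_class_set
        assert wset.features.shape[1] == 63

    def test_normalization_idempotent(self):
        rng = np.random.default_rng(2)
        w = rng.standard_normal((20, 64))
        n1, _ = minmax_normalize(w)
        n2, _ = minmax_normalize(n1)
        np.testing.assert_allclose(n1, n2, atol=1e-14)

    def test_gradient_affine_invariance(self):
        rng = np.random.default_rng(3)
        w = rng.standard_normal((10, 64))
        a = normalize_and_gradient(self._wset(w))
        b = normalize_and_gradient(self._wset(2.5 * w - 7.0))
        np.testing.assert_allclose(a.features, b.features, atol=1e-9)


class TestRoundTrip:
    def test_detection_recovers_clear_spikes(self):
        """detect+extract on a simulated trace finds >= 95% of SNR >= 8
        ground-truth spikes within +/- 2 samples (clear margin over the
        5-sigma threshold; behavior near the SNR 6 boundary is
        characterized in the acceptance suite)."""
        cfg = simulate.SimConfig(n_neurons=5, duration_s=20.0,
                                 noise_sigma=2.0, target_snr_range=(4, 12),
                                 seed=11)
        trace, truth = simulate.generate_recording(cfg)
        wset = preprocess_trace(trace, cfg.sampling_rate_hz)
        det_samples = np.round(wset.times_ms / 1e3 * cfg.sampling_rate_hz)
        truth_samples = np.round(truth.spike_times_ms / 1e3
                                 * cfg.sampling_rate_hz)
        strong = truth.snr >= 8.0
        assert strong.sum() > 100
        hits = sum(np.min(np.abs(det_samples - ts)) <= 2
                   for ts in truth_samples[strong])
        assert hits / strong.sum() >= 0.95
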