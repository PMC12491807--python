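"""Calcium stage: unmixing, traces, dF/F, peak and 3-D event detection,
spectral summaries."""

import numpy as np
import pytest

import periflow as pf
from periflow.calcium import FluorescenceMovie, ROIMeta, ROISet
from periflow.synth import SynthConfig


def _movie(data, rate=10.0, names=None):
    n_ch = 1 if data.ndim == 3 else data.shape[-1]
    names = names or tuple(f"ch{i}" for i in range(n_ch))
    return FluorescenceMovie(data=data, frame_rate=rate, channel_names=names)


class TestUnmix:
    def test_identity_matrix_is_noop(self, rng):
        data = rng.uniform(10, 100, (5, 8, 8, 2))
        m = _movie(data)
        out = pf.unmix_channels(m, np.eye(2))
        assert np.allclose(out.data, data)

    def test_singular_matrix_raises(self, rng):
        m = _movie(rng.uniform(0, 1, (3, 4, 4, 2)))
        with pytest.raises(np.linalg.LinAlgError):
            pf.unmix_channels(m, np.array([[1.0, 0.0], [1.0, 0.0]]))

    def test_forward_mix_then_invert_recovers(self, rng):
        clean = rng.uniform(10, 100, (4, 6, 6, 2))
        mix = np.array([[1.0, 0.2], [0.2, 1.0]])
        observed = np.einsum("tyxc,dc->tyxd", clean, mix)
        rec = pf.unmix_channels(_movie(observed), mix)
        assert np.allclose(rec.data, clean, atol=1e-9)


class TestRoiTrace:
    def test_uniform_frame_mean(self):
        m = _movie(np.full((4, 5, 5), 7.0))
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True
        assert np.allclose(pf.extract_roi_trace(m, mask), 7.0)

    def test_two_pixel_mean(self):
        data = np.zeros((1, 2, 2))
        data[0, 0, 0], data[0, 0, 1] = 3.0, 5.0
        mask = np.zeros((2, 2), bool)
        mask[0, :] = True
        assert pf.extract_roi_trace(_movie(data), mask)[0] == 4.0

    def test_planted_blob_sets_trace_maximum(self):
        cfg = SynthConfig(seed=1, duration=20.0, noise_sd=0.0)
        movie, rois, _ = pf.gen_calcium_movie(cfg, events={1: [(10.0, 0.8)]})
        tr = pf.extract_roi_trace(movie, 1, rois)
        assert abs(np.argmax(tr) / cfg.frame_rate - 10.0) < 0.5

    def test_empty_roi_raises(self):
        m = _movie(np.ones((2, 4, 4)))
        with pytest.raises(ValueError):
            pf.extract_roi_trace(m, np.zeros((4, 4), bool))


class TestDff:
    def test_constant_trace_gives_zero_dff(self):
        tr = pf.compute_dff(np.full(100, 50.0), 10.0)
        assert np.allclose(tr.dff, 0.0)
        assert tr.f0 == 50.0

    def test_arithmetic(self):
        raw = np.full(100, 100.0)
        raw[80] = 150.0
        tr = pf.compute_dff(raw, 10.0)
        assert tr.dff[80] == pytest.approx(0.5)

    @pytest.mark.parametrize("c", [0.5, 3.0, 117.0])
    def test_scale_invariance(self, rng, c):
        raw = rng.uniform(50, 150, 200)
        a = pf.compute_dff(raw, 10.0)
        b = pf.compute_dff(c * raw, 10.0)
        assert np.allclose(a.dff, b.dff)

    def test_planted_amplitude_recovered(self):
        cfg = SynthConfig(seed=2, duration=60.0, noise_sd=0.0)
        raw, truth = pf.gen_calcium_trace(cfg, 2.0, amp_mean=0.6)
        if len(truth.event_times) == 0:
            pytest.skip("no events drawn at this seed")
        tr = pf.compute_dff(raw, cfg.frame_rate)
        # instant-rise kernel sampled at frame times: peak within one
        # frame's decay of the planted amplitude
        assert tr.dff.max() == pytest.approx(
            0.6, rel=1 - np.exp(-1 / cfg.frame_rate))

    def test_non_positive_f0_raises(self):
        with pytest.raises(ValueError):
            pf.compute_dff(np.zeros(100), 10.0)


class TestF0Basal:
    def test_constant(self):
        assert pf.compute_f0_basal(np.full(100, 10.0), 10.0) == 10.0

    def test_ramp_mean_of_first_window(self):
        raw = np.arange(720, dtype=float)
        got = pf.compute_f0_basal(raw, 12.0, window_s=2.5)
        assert got == pytest.approx(raw[:30].mean())

    def test_per_roi_values(self):
        labels = np.zeros((8, 8), np.int32)
        labels[0, 0], labels[1, 1] = 1, 2
        rois = ROISet(label_image=labels,
                      meta={1: ROIMeta("soma"), 2: ROIMeta("process")})
        data = np.zeros((40, 8, 8))
        data[:, 0, 0], data[:, 1, 1] = 5.0, 9.0
        out = pf.compute_f0_basal(_movie(data), rois=rois)
        assert out == {1: 5.0, 2: 9.0}


class TestDetectPeaks:
    def test_flat_trace_no_events(self):
        tr = pf.compute_dff(np.full(720, 100.0), 12.0)
        events, summary = pf.detect_peaks(tr)
        assert events == []
        assert summary["events_per_min"] == 0.0

    def test_recovery_at_snr8(self):
        """6 planted events/min at SNR 8: rate within 1/min, amplitudes
        within 15% of truth (averaged over seeds)."""
        errs, amps = [], []
        for seed in range(8):
            cfg = SynthConfig(seed=seed, duration=60.0, noise_sd=100 * 0.5 / 8)
            raw, truth = pf.gen_calcium_trace(cfg, 6.0, amp_mean=0.5)
            _, summary = pf.detect_peaks(pf.compute_dff(raw, cfg.frame_rate))
            errs.append(summary["events_per_min"] - len(truth.event_times))
            amps.append(summary["amp_mean"])
        assert abs(np.mean(errs)) <= 1.0
        assert abs(np.mean(amps) - 0.5) <= 0.15 * 0.5

    def test_adjacent_identical_peaks_count_once(self):
        t = np.arange(0, 60, 1 / 12.0)
        dff = np.exp(-0.5 * ((t - 30.0) / 0.15) ** 2) \
            + np.exp(-0.5 * ((t - 30.5) / 0.15) ** 2)
        tr = pf.CalciumTrace(dff=dff + 1e-3, f0=100.0, sampling_rate=12.0)
        events, _ = pf.detect_peaks(tr, min_separation_s=1.0)
        assert len(events) == 1

    def test_band_outside_nyquist_raises(self):
        tr = pf.compute_dff(np.full(720, 100.0), 12.0)
        with pytest.raises(ValueError):
            pf.detect_peaks(tr, band_hz=(0.01, 7.0))


class TestDetectEvents3d:
    def _single(self, movie):
        return FluorescenceMovie(movie.channel(0), movie.frame_rate, ("ca",))

    def test_noise_free_event_free_is_silent(self):
        cfg = SynthConfig(seed=0, duration=20.0, noise_sd=0.0)
        movie, rois, _ = pf.gen_calcium_movie(cfg, events={})
        freq, events = pf.detect_events_3d(self._single(movie), rois)
        assert all(v == 0 for v in freq.values())
        assert events == []

    def test_planted_blobs_recovered_at_snr5(self):
        amp, f0 = 0.8, 100.0
        cfg = SynthConfig(seed=6, duration=60.0, noise_sd=amp * f0 / 5)
        times = [8.0, 18.0, 28.0, 38.0, 48.0]
        movie, rois, _ = pf.gen_calcium_movie(
            cfg, events={1: [(t, amp) for t in times]}, f0_cell=f0)
        freq, _ = pf.detect_events_3d(self._single(movie), rois)
        assert freq[1] == pytest.approx(5.0, abs=1.0)

    def test_blob_outside_vessel_mask_excluded(self):
        ny = nx = 64
        labels = np.zeros((ny, nx), np.int32)
        labels[30:34, 10:20] = 1
        vessel = np.zeros((ny, nx), bool)
        vessel[28:36, :] = True
        rois = ROISet(labels, {1: ROIMeta("soma")}, vessel_mask=vessel)
        data = np.full((120, ny, nx), 10.0)
        data += np.random.default_rng(0).normal(0, 1.0, data.shape)
        data[60:66, 5:9, 50:54] += 50.0  # far off the vessel
        freq, events = pf.detect_events_3d(_movie(data, 12.0), rois)
        assert freq[1] == 0.0
        assert all(e.roi_ref != 1 for e in events)

    def test_count_monotone_in_threshold(self):
        amp, f0 = 0.8, 100.0
        cfg = SynthConfig(seed=9, duration=30.0, noise_sd=amp * f0 / 5)
        movie, rois, _ = pf.gen_calcium_movie(
            cfg, events={1: [(8.0, amp), (18.0, amp)], 2: [(12.0, amp)]},
            f0_cell=f0)
        single = self._single(movie)
        counts = []
        for k in (2.0, 3.0, 4.0, 6.0, 50.0):
            _, events = pf.detect_events_3d(single, rois, k=k)
            counts.append(len(events))
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        assert counts[-1] == 0  # k -> infinity silences everything

    def test_two_channel_movie_rejected(self):
        cfg = SynthConfig(duration=5.0)
        movie, rois, _ = pf.gen_calcium_movie(cfg, events={})
        with pytest.raises(ValueError):
            pf.detect_events_3d(movie, rois)


class TestPsdPeak:
    def test_pure_sinusoid_peaks_at_nearest_bin(self):
        t = np.arange(0, 60, 1 / 12.0)
        spec = pf.compute_psd_peak(np.sin(2 * np.pi * 0.1 * t),
                                   sampling_rate=12.0)
        bins = spec.freqs
        assert spec.peak_freq == bins[np.argmin(np.abs(bins - 0.1))]

    def test_larger_amplitude_wins(self):
        t = np.arange(0, 120, 1 / 12.0)
        x = np.sin(2 * np.pi * 0.05 * t) + 0.5 * np.sin(2 * np.pi * 0.3 * t)
        spec = pf.compute_psd_peak(x, sampling_rate=12.0)
        assert spec.peak_freq == pytest.approx(0.05, abs=1 / 120.0)

    def test_parseval_consistency(self, rng):
        x = rng.normal(0, 1, 720)
        spec = pf.compute_psd_peak(x, sampling_rate=12.0)
        df = spec.freqs[1] - spec.freqs[0]
        xc = x - x.mean()
        assert np.sum(spec.psd) * df == pytest.approx(xc.var(), rel=0.01)

    def test_white_noise_peak_spreads_over_band(self):
        peaks = []
        for seed in range(400):
            x = np.random.default_rng(seed).normal(0, 1, 720)
            peaks.append(pf.compute_psd_peak(x, sampling_rate=12.0).peak_freq)
        peaks = np.asarray(peaks)
        assert peaks.min() >= 0.01 and peaks.max() <= 0.5
        # roughly uniform over ~29 band bins: no bin should dominate
        _, counts = np.unique(peaks, return_counts=True)
        assert len(counts) > 20
        assert counts.max() / len(peaks) < 0.10

    def test_unresolvable_band_raises(self):
        with pytest.raises(ValueError):
            pf.compute_psd_peak(np.ones(24), sampling_rate=12.0,
                                band=(0.01, 0.02))
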