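"""Line-scan stage: FWHM diameter, vasomotion, velocimetry, flux,
cleaning rules, resampling."""

import numpy as np
import pytest
from scipy import stats as sps

import periflow as pf
from periflow.linescan import (FLAG_INVALID, HemoTrace, Kymograph,
                               fwhm_profile)
from periflow.synth import SynthConfig

GAUSS_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))


def _kym(data, lp=0.002, ps=1.0, orient="perpendicular"):
    return Kymograph(data=np.asarray(data, float), line_period=lp,
                     pixel_size=ps, orientation=orient)


class TestFwhm:
    def test_rectangular_plateau_exact(self):
        prof = np.zeros(128)
        prof[59:69] = 1.0
        width, ok = fwhm_profile(prof)
        assert ok and width == pytest.approx(10.0, abs=1e-9)

    def test_gaussian_closed_form(self):
        x = np.arange(128, dtype=float)
        prof = np.exp(-((x - 63.5) ** 2) / (2 * 3.0**2))
        width, ok = fwhm_profile(prof)
        assert ok
        assert width == pytest.approx(GAUSS_FWHM * 3.0, rel=0.01)

    def test_vessel_filling_scan_flagged(self):
        width, ok = fwhm_profile(np.ones(64))
        assert not ok

    def test_diameter_trace_from_rect_kymograph(self):
        cfg = SynthConfig(seed=0, duration=5.0, noise_sd=0.0, pixel_size=1.0)
        kym, _ = pf.gen_diameter_kymograph(cfg, d0=10.0)
        d = pf.diameter_from_kymograph(kym)
        assert np.allclose(d.values, 10.0)

    def test_sinusoidal_recovery_at_snr10(self):
        cfg = SynthConfig(seed=1, duration=60.0, noise_sd=0.1, pixel_size=1.0)
        kym, truth = pf.gen_diameter_kymograph(cfg, d0=10.0, vaso_amp=0.1,
                                               vaso_freq=0.1, edge_blur=1.0)
        d = pf.diameter_from_kymograph(kym, window_lines=50)
        expect = np.interp(d.times, truth.diameter_times, truth.diameter_values)
        rms = np.sqrt(np.mean((d.values - expect) ** 2))
        assert rms < 0.2

    def test_invariance_to_intensity_scale_and_offset(self):
        cfg = SynthConfig(seed=2, duration=5.0, noise_sd=0.0, pixel_size=1.0)
        kym, _ = pf.gen_diameter_kymograph(cfg, d0=12.0, edge_blur=1.5)
        d1 = pf.diameter_from_kymograph(kym)
        kym2 = _kym(3.0 * kym.data + 40.0, lp=kym.line_period)
        d2 = pf.diameter_from_kymograph(kym2)
        assert np.allclose(d1.values, d2.values)


def _brute_cycle_count(t, v, prominence, min_sep_s):
    """Independent oracle: local maxima by direct neighborhood scan."""
    peaks = []
    k = int(round(min_sep_s / (t[1] - t[0])))
    for i in range(1, len(v) - 1):
        lo, hi = max(i - k, 0), min(i + k + 1, len(v))
        if v[i] == v[lo:hi].max() and v[i] - v[lo:hi].min() >= prominence:
            if not peaks or i - peaks[-1] >= k:
                peaks.append(i)
    excursions = []
    for j, p in enumerate(peaks):
        lo = peaks[j - 1] if j else 0
        hi = peaks[j + 1] if j + 1 < len(peaks) else len(v) - 1
        excursions.append(v[p] - v[lo:hi + 1].min())
    return len(peaks), (np.mean(excursions) / v.mean() if peaks else 0.0)


class TestVasomotion:
    def _trace(self, f=0.1, amp=1.0, d0=10.0, dur=60.0, extra=None):
        t = np.arange(0, dur, 0.1)
        v = d0 + amp * np.sin(2 * np.pi * f * t)
        if extra is not None:
            v = v + extra[1] * np.sin(2 * np.pi * extra[0] * t)
        return HemoTrace("diameter", t, v)

    def test_pure_sinusoid_frequency_and_index(self):
        out = pf.vasomotion_metrics(self._trace())
        assert out.frequency == pytest.approx(6.0, abs=1e-9)
        assert out.vasomotor_index == pytest.approx(0.2, rel=0.02)
        assert out.peak_freq_hz == pytest.approx(0.1, abs=1 / 60.0)

    def test_constant_diameter_is_quiet(self):
        t = np.arange(0, 60, 0.1)
        out = pf.vasomotion_metrics(HemoTrace("diameter", t, np.full(len(t), 10.0)))
        assert out.frequency == 0.0
        assert out.vasomotor_index == 0.0

    def test_two_sinusoids_match_brute_force_count(self):
        tr = self._trace(extra=(0.3, 0.2))
        out = pf.vasomotion_metrics(tr)
        n, idx = _brute_cycle_count(tr.times, tr.values,
                                    prominence=0.05 * tr.values.mean(),
                                    min_sep_s=2.0)
        assert out.frequency == pytest.approx(n / 60.0 * 60.0, abs=1e-9)
        assert out.vasomotor_index == pytest.approx(idx, rel=0.05)

    def test_short_trace_rejected(self):
        t = np.arange(0, 10, 0.1)
        with pytest.raises(ValueError):
            pf.vasomotion_metrics(HemoTrace("diameter", t, 10 + np.sin(t)))


class TestVelocity:
    def test_noise_free_recovery_within_5pct(self):
        cfg = SynthConfig(seed=4, duration=0.8, noise_sd=0.0, pixel_size=0.5)
        kym, _ = pf.gen_velocity_kymograph(cfg, velocity=2.0, flux_rate=8.0)
        vel = pf.velocity_from_kymograph(kym)
        assert abs(np.nanmedian(vel.values) - 2.0) / 2.0 < 0.05

    def test_stall_returns_near_zero(self):
        cfg = SynthConfig(seed=5, duration=2.0, noise_sd=0.02)
        kym, _ = pf.gen_velocity_kymograph(cfg, velocity=2.0, flux_rate=30.0,
                                           stall_epochs=[(0.5, 1.5)])
        vel = pf.velocity_from_kymograph(kym)
        mid = (vel.times > 0.65) & (vel.times < 1.35)
        assert np.nanmedian(np.abs(vel.values[mid])) < 0.05

    def test_position_flip_negates_velocity(self):
        cfg = SynthConfig(seed=6, duration=0.8, noise_sd=0.0)
        kym, _ = pf.gen_velocity_kymograph(cfg, velocity=2.0, flux_rate=8.0)
        flipped = _kym(np.asarray(kym.data)[:, ::-1], lp=kym.line_period,
                       ps=kym.pixel_size, orient="parallel")
        v1 = np.nanmedian(pf.velocity_from_kymograph(kym).values)
        v2 = np.nanmedian(pf.velocity_from_kymograph(flipped).values)
        assert v2 == pytest.approx(-v1, rel=0.05)

    def test_time_origin_shift_invariance(self):
        cfg = SynthConfig(seed=7, duration=1.0, noise_sd=0.0)
        kym, _ = pf.gen_velocity_kymograph(cfg, velocity=1.0, flux_rate=10.0)
        shifted = _kym(np.asarray(kym.data)[100:], lp=kym.line_period,
                       ps=kym.pixel_size, orient="parallel")
        v1 = np.nanmedian(pf.velocity_from_kymograph(kym).values)
        v2 = np.nanmedian(pf.velocity_from_kymograph(shifted).values)
        assert v2 == pytest.approx(v1, rel=0.05)

    def test_window_too_short_raises(self):
        cfg = SynthConfig(seed=0, duration=0.5)
        kym, _ = pf.gen_velocity_kymograph(cfg, 1.0, 5.0)
        with pytest.raises(ValueError):
            pf.velocity_from_kymograph(kym, window_lines=10)


class TestFlux:
    def test_fifty_regular_streaks_exactly_five_per_second(self):
        nlines, npos = 5000, 64  # 10 s at 2 ms/line
        data = np.ones((nlines, npos))
        for k in range(50):
            start = 40 + k * 99
            data[start:start + 4, :] = 0.5
        fx = pf.flux_from_kymograph(_kym(data, orient="parallel"))
        assert fx.values.mean() == pytest.approx(5.0, abs=1e-9)

    def test_zero_streaks_zero_flux(self):
        fx = pf.flux_from_kymograph(_kym(np.ones((1000, 64)), orient="parallel"))
        assert np.all(fx.values == 0.0)
        assert np.all(fx.flags == FLAG_INVALID)  # zero dynamic range flagged

    def test_poisson_arrivals_within_10pct(self):
        cfg = SynthConfig(seed=3, duration=20.0, noise_sd=0.08, pixel_size=0.5)
        kym, truth = pf.gen_velocity_kymograph(cfg, velocity=2.0, flux_rate=8.0)
        fx = pf.flux_from_kymograph(kym)
        px_per_line = 2.0 * 1e3 * 0.002 / 0.5
        entries = np.concatenate([truth.extras["pre_entries"],
                                  truth.cell_entry_times])
        cross = entries / 0.002 + (128 + 6) / px_per_line
        truth_rate = np.sum((cross >= 0) & (cross < kym.n_lines)) / 20.0
        assert abs(fx.values.mean() - truth_rate) / truth_rate < 0.10


def _esd_oracle_outliers(x, k_max=15, alpha=0.05):
    """Sequential ESD with critical values recomputed from the
    t-distribution, written independently of the implementation."""
    work = list(x)
    order = []
    n = len(x)
    n_out = 0
    for i in range(1, k_max + 1):
        arr = np.asarray(work)
        mu, sd = arr.mean(), arr.std(ddof=1)
        j = int(np.argmax(np.abs(arr - mu)))
        r_i = abs(arr[j] - mu) / sd
        m = n - i + 1
        t_crit = sps.t.ppf(1 - alpha / (2 * m), m - 2)
        lam = (m - 1) * t_crit / np.sqrt((m - 2 + t_crit**2) * m)
        order.append(work.pop(j))
        if r_i > lam:
            n_out = i
    return set(np.round(order[:n_out], 12))


class TestCleanTrace:
    def test_deviant_sample_replaced_by_neighbor_mean(self):
        tr = HemoTrace("diameter", np.arange(4.0), np.array([5.0, 5, 500, 5]))
        out = pf.clean_trace(tr, bounds=(0.0, 100.0))
        assert np.array_equal(out.values, [5.0, 5.0, 5.0, 5.0])
        assert out.flags[2] == 1

    def test_esd_removes_exactly_planted_outliers(self, rng):
        x = np.concatenate([rng.normal(2.0, 0.1, 100), [10.0, 10.0, 10.0]])
        idx = pf.generalized_esd(x)
        assert sorted(idx) == [100, 101, 102]
        assert _esd_oracle_outliers(x) == set(np.round(x[idx], 12))

    def test_esd_clean_trace_drops_outliers_and_records(self, rng):
        vals = np.concatenate([rng.normal(2.0, 0.1, 100), [30.0, 30.0]])
        tr = HemoTrace("velocity", np.arange(102.0), vals)
        out = pf.clean_trace(tr)
        assert len(out.values) == 100
        assert out.meta["n_outliers_removed"] == 2

    def test_clean_is_noop_on_good_trace(self, rng):
        vals = rng.normal(2.0, 0.1, 50)
        tr = HemoTrace("velocity", np.arange(50.0), vals)
        out = pf.clean_trace(tr)
        assert np.array_equal(out.values, vals)
        assert out.meta["n_outliers_removed"] == 0

    def test_mostly_invalid_trace_rejected(self):
        tr = HemoTrace("diameter", np.arange(4.0), np.array([900.0, 900, 900, 5]))
        with pytest.raises(ValueError):
            pf.clean_trace(tr, bounds=(0.0, 100.0))

    def test_never_adds_samples_never_touches_good_ones(self, rng):
        vals = np.concatenate([rng.normal(5.0, 0.5, 60), [400.0]])
        tr = HemoTrace("diameter", np.arange(61.0), vals)
        out = pf.clean_trace(tr, bounds=(0.0, 50.0))
        assert len(out.values) <= len(tr.values)
        assert np.array_equal(out.values[:60], vals[:60])


class TestResampleSmooth:
    def test_constant_stays_constant(self):
        tr = HemoTrace("diameter", np.arange(0, 30, 0.5), np.full(60, 8.0))
        out = pf.resample_smooth(tr)
        assert np.allclose(out.values, 8.0)
        assert np.allclose(np.diff(out.times), 0.1)

    def test_linear_ramp_preserved_away_from_edges(self):
        t = np.arange(0, 30, 0.5)
        tr = HemoTrace("diameter", t, 2.0 * t)
        out = pf.resample_smooth(tr)
        inner = slice(10, -10)
        assert np.allclose(out.values[inner], 2.0 * out.times[inner], atol=1e-9)

    def test_sinusoid_attenuation_matches_window_response(self):
        f, fs = 0.1, 10.0
        t = np.arange(0, 300, 0.1)
        tr = HemoTrace("diameter", t, 10.0 + np.sin(2 * np.pi * f * t))
        out = pf.resample_smooth(tr)
        n_win = 11  # symmetric 1-s window at 10 samples/s
        expect = abs(np.sin(np.pi * f * n_win / fs)
                     / (n_win * np.sin(np.pi * f / fs)))
        inner = slice(50, -50)
        got = (out.values[inner].max() - out.values[inner].min()) / 2.0
        assert got == pytest.approx(expect, rel=0.02)
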