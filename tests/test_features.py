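"""Event waveform features, AUC power-law fits, Fisher-z comparison, KDE."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from laminar_swr.features import (compare_correlation_slopes, compute_auc,
                                  density_contours, loglog_fit,
                                  select_median_events, sw_frequency,
                                  waveform_features)

FS = 600.0


class TestAuc:
    def test_zero_waveform(self):
        assert compute_auc(np.zeros(100), FS) == 0.0

    def test_constant_waveform_exact(self):
        c, dur = 3.0, 0.5
        n = int(dur * FS) + 1
        assert compute_auc(np.full(n, -c), FS) == pytest.approx(
            c * dur, rel=1e-12)

    def test_sine_period_matches_analytic_integral(self):
        t = np.arange(int(0.1 * FS) + 1) / FS
        wave = np.sin(2 * np.pi * 10.0 * t)
        assert compute_auc(wave, FS) == pytest.approx(2.0 / (10 * np.pi),
                                                      rel=0.01)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            compute_auc(np.array([1.0]), FS)

    def test_additive_under_concatenation(self, rng):
        x = rng.normal(size=601)
        whole = compute_auc(x, FS)
        left = compute_auc(x[:301], FS)
        right = compute_auc(x[300:], FS)
        assert whole == pytest.approx(left + right, rel=1e-9)

    def test_linear_in_amplitude_gain(self, rng):
        x = rng.normal(size=300)
        assert compute_auc(3.0 * x, FS) == pytest.approx(
            3.0 * compute_auc(x, FS), rel=1e-12)


class TestWaveformFeatures:
    def test_unit_tone_features(self):
        cycles = 15
        n = int(cycles / 150.0 * FS)
        t = np.arange(n) / FS
        amp, mfreq, power, n_peaks = waveform_features(
            np.sin(2 * np.pi * 150.0 * t), FS)
        assert amp == pytest.approx(1.0, abs=0.05)
        assert mfreq == pytest.approx(150.0, abs=1.0)
        assert power == pytest.approx(0.5, abs=0.02)
        assert n_peaks == cycles

    def test_constant_waveform(self):
        amp, _, power, n_peaks = waveform_features(np.full(100, 2.0), FS)
        assert amp == pytest.approx(2.0, rel=0.05)
        assert power == pytest.approx(4.0)
        assert n_peaks == 0

    def test_equal_mix_mean_freq_is_midpoint(self):
        t = np.arange(int(1.0 * FS)) / FS
        x = np.sin(2 * np.pi * 100 * t) + np.sin(2 * np.pi * 200 * t)
        _, mfreq, _, _ = waveform_features(x, FS)
        assert mfreq == pytest.approx(150.0, abs=2.0)


class TestSwFrequency:
    def test_pure_tone_recovered(self):
        t = np.arange(int(10 * FS)) / FS
        x = np.sin(2 * np.pi * 8.0 * t)
        f, flag = sw_frequency(x, FS, peak_s=5.0, start_s=4.8, end_s=5.2)
        assert not flag
        assert f == pytest.approx(8.0, abs=2.0)

    def test_two_tone_symmetry(self):
        t = np.arange(int(10 * FS)) / FS
        x = np.sin(2 * np.pi * 5 * t) + np.sin(2 * np.pi * 15 * t)
        f, _ = sw_frequency(x, FS, peak_s=5.0, start_s=4.0, end_s=6.0)
        assert f == pytest.approx(10.0, abs=1.5)

    def test_zero_trace_flagged(self):
        x = np.zeros(int(10 * FS))
        f, flag = sw_frequency(x, FS, peak_s=5.0, start_s=4.9, end_s=5.1)
        assert f == 0.0 and flag

    def test_peak_outside_trace_rejected(self):
        with pytest.raises(ValueError):
            sw_frequency(np.zeros(600), FS, peak_s=100.0, start_s=99.0,
                         end_s=101.0)


class TestLogLogFit:
    def test_identity(self):
        x = np.linspace(1, 10, 50)
        fit = loglog_fit(x, x)
        assert fit.slope == pytest.approx(1.0, abs=1e-9)
        assert fit.intercept == pytest.approx(0.0, abs=1e-9)
        assert fit.r == pytest.approx(1.0, abs=1e-9)

    def test_exact_power_law(self):
        x = np.linspace(1, 10, 50)
        fit = loglog_fit(x, 10.0 * x ** 2)
        assert fit.slope == pytest.approx(2.0, abs=1e-9)
        assert fit.intercept == pytest.approx(1.0, abs=1e-9)

    def test_noisy_exponent_recovery(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(1.0, 100.0, size=500)
        y = 3.0 * x ** 1.5 * 10 ** rng.normal(0.0, 0.1, size=500)
        fit = loglog_fit(x, y)
        assert fit.slope == pytest.approx(1.5, abs=0.05)
        assert fit.n == 500

    def test_nonpositive_values_dropped_and_counted(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 0.0])
        y = np.array([1.0, 2.0, 3.0, -4.0, 5.0])
        fit = loglog_fit(x, y)
        assert fit.n == 3 and fit.n_dropped == 2

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            loglog_fit(np.array([1.0, 2.0]), np.array([1.0, 2.0]))


class TestFisherZ:
    def test_equal_correlations_give_zero(self):
        z, p = compare_correlation_slopes(0.7, 50, 0.7, 50)
        assert z == 0.0 and p == pytest.approx(1.0)

    def test_closed_form_value(self):
        # independent evaluation: (atanh .9 - atanh .5) / sqrt(2/97)
        z, p = compare_correlation_slopes(0.9, 100, 0.5, 100)
        expected = (np.arctanh(0.9) - np.arctanh(0.5)) / np.sqrt(2.0 / 97.0)
        assert z == pytest.approx(expected, rel=1e-12)
        assert z == pytest.approx(6.43, abs=0.01)
        assert p < 1e-9

    def test_antisymmetric(self):
        z1, _ = compare_correlation_slopes(0.8, 40, 0.3, 60)
        z2, _ = compare_correlation_slopes(0.3, 60, 0.8, 40)
        assert z1 == pytest.approx(-z2)

    def test_degenerate_r_rejected(self):
        with pytest.raises(ValueError):
            compare_correlation_slopes(1.0, 10, 0.5, 10)


class TestMedianSelection:
    def _events(self, amps):
        return pd.DataFrame({"type": "SWR",
                             "sp_amplitude_uv": amps,
                             "peak_s": np.arange(len(amps), dtype=float)})

    def test_k_at_least_n_returns_all(self):
        ev = self._events([1.0, 2.0, 3.0])
        assert len(select_median_events(ev, 10)) == 3

    def test_closest_to_median_kept(self):
        ev = self._events([1.0, 2.0, 3.0, 4.0, 100.0])
        out = select_median_events(ev, 3)
        assert sorted(out["sp_amplitude_uv"]) == [2.0, 3.0, 4.0]

    def test_ties_break_by_earlier_peak(self):
        ev = self._events([5.0] * 6)
        out = select_median_events(ev, 3)
        assert list(out["peak_s"]) == [0.0, 1.0, 2.0]


class TestDensityContours:
    def test_equal_mass_levels_on_gaussian(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=(2, 2000))
        xx, yy, dens, levels = density_contours(x, y, n_levels=3)
        cell = (xx[0, 1] - xx[0, 0]) * (yy[1, 0] - yy[0, 0])
        total = dens.sum() * cell
        assert levels == sorted(levels)
        for i, lev in enumerate(levels):
            mass = dens[dens >= lev].sum() * cell / total
            assert mass == pytest.approx((3 - i) / 3.0, abs=0.05)

    def test_two_blobs_have_disjoint_innermost_contours(self):
        rng = np.random.default_rng(4)
        x = np.concatenate([rng.normal(-5, 0.5, 500), rng.normal(5, 0.5, 500)])
        y = rng.normal(size=1000) * 0.5
        _, _, dens, levels = density_contours(x, y, n_levels=3)
        n_regions = ndimage.label(dens >= levels[-1])[1]
        assert n_regions == 2

    def test_single_level_encloses_everything(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=(2, 200))
        xx, yy, dens, levels = density_contours(x, y, n_levels=1)
        assert len(levels) == 1
        cell = (xx[0, 1] - xx[0, 0]) * (yy[1, 0] - yy[0, 0])
        mass = dens[dens >= levels[0]].sum() * cell / (dens.sum() * cell)
        assert mass >= 0.999

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            density_contours(np.arange(5.0), np.arange(5.0), 3)
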