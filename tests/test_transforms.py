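"""Waveform renders, scalogram, WVD/SPWVD, and the normalization chain."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy.signal import hilbert

from hfopipe import DegenerateCohortError, DegenerateEpochError
from hfopipe.detector import FAST_RIPPLE, RIPPLE
from hfopipe.synth import make_hfo_kernel
from hfopipe.transforms import (
    CurveC,
    SmoothingWindows,
    TfMatrix,
    adjust_aspwvd,
    crop_display,
    curve_c,
    fit_cohort,
    morlet_scalogram,
    normalize_per_frequency,
    render_filtered,
    render_original,
    renormalize,
    spwvd,
    wvd,
)

FS = 2000.0


def _epoch_with_burst(amp=800.0, freq=140.0, seed=0):
    rng = np.random.default_rng(seed)
    epoch = rng.normal(0, 5.0, 10_000)
    kernel = make_hfo_kernel(freq, 8, amp, FS)
    start = 5000 - len(kernel) // 2
    epoch[start : start + len(kernel)] += kernel
    return epoch


class TestWaveformRenders:
    def test_fixed_original_limits(self):
        trace, spec = render_original(_epoch_with_burst(800.0), RIPPLE, "fixed")
        assert spec.limits == (-1000.0, 1000.0)
        assert len(trace) == 400  # 200 ms at 2 kHz
        assert np.max(np.abs(trace)) < 1000  # no clipping needed at 800 µV

    def test_fitted_alpha_is_slice_max(self):
        epoch = _epoch_with_burst(800.0)
        trace, spec = render_original(epoch, RIPPLE, "fitted")
        assert spec.fitted_alpha == pytest.approx(np.max(np.abs(trace)))
        assert spec.limits == (-spec.fitted_alpha, spec.fitted_alpha)

    def test_fitted_render_scale_invariant(self):
        epoch = _epoch_with_burst(800.0)
        t1, s1 = render_original(epoch, RIPPLE, "fitted")
        t2, s2 = render_original(2.0 * epoch, RIPPLE, "fitted")
        np.testing.assert_allclose(t2 / s2.fitted_alpha, t1 / s1.fitted_alpha)

    def test_filtered_fixed_limits_per_band(self):
        epoch = _epoch_with_burst(60.0, freq=250.0)
        _, spec_fr = render_filtered(epoch, FAST_RIPPLE, "fixed")
        assert spec_fr.limits == (-10.0, 10.0)
        _, spec_r = render_filtered(epoch, RIPPLE, "fixed")
        assert spec_r.limits == (-50.0, 50.0)

    def test_filtered_fr_slice_length(self):
        trace, _ = render_filtered(np.zeros(10_000), FAST_RIPPLE, "fixed")
        assert len(trace) == 200  # 100 ms at 2 kHz
        assert not trace.any()

    def test_zero_slice_alpha_fallback(self):
        _, spec = render_original(np.zeros(10_000), RIPPLE, "fitted")
        assert spec.fitted_alpha == 1.0


class TestMorletScalogram:
    def test_tone_frequency_recovered(self):
        t = np.arange(10_000) / FS
        tf = morlet_scalogram(np.cos(2 * np.pi * 140 * t), RIPPLE, FS)
        profile = tf.values.mean(axis=1)
        assert abs(tf.freqs[np.argmax(profile)] - 140) <= 1

    def test_zero_epoch(self):
        tf = morlet_scalogram(np.zeros(10_000), RIPPLE, FS)
        assert not tf.values.any()

    def test_energy_is_quadratic(self):
        epoch = _epoch_with_burst(50.0)
        a = morlet_scalogram(epoch, RIPPLE, FS)
        b = morlet_scalogram(2.0 * epoch, RIPPLE, FS)
        np.testing.assert_allclose(b.values, 4.0 * a.values, rtol=1e-10)

    def test_display_crop(self):
        tf = morlet_scalogram(np.zeros(10_000), RIPPLE, FS)
        assert tf.times_ms[-1] - tf.times_ms[0] <= 200.0
        assert tf.freqs[0] >= 80 and tf.freqs[-1] <= 200

    def test_tone_amplitude_calibration(self):
        # unit-amplitude tone -> energy ~ 1 at the matched row
        t = np.arange(10_000) / FS
        tf = morlet_scalogram(np.cos(2 * np.pi * 150 * t), RIPPLE, FS)
        row = np.argmin(np.abs(tf.freqs - 150))
        assert tf.values[row].max() == pytest.approx(1.0, rel=0.05)


class TestWvd:
    def test_time_marginal_recovers_instantaneous_power(self):
        n = 256
        t = (np.arange(n) - n / 2) / FS
        atom = np.exp(-(t**2) / (2 * 0.01**2)) * np.cos(2 * np.pi * 140 * t)
        tf = wvd(atom, FS)
        marginal = tf.values.sum(axis=0) / n
        power = np.abs(hilbert(atom)) ** 2
        np.testing.assert_allclose(marginal, power, atol=1e-10)

    def test_tone_concentrates_at_frequency(self):
        x = np.cos(2 * np.pi * 140 * np.arange(2000) / FS)
        tf = wvd(x, FS)
        row = np.argmax(tf.values.max(axis=1))
        assert abs(tf.freqs[row] - 140) <= 0.5

    def test_zero_signal(self):
        assert not wvd(np.zeros(128), FS).values.any()

    def test_bilinearity(self):
        x = _epoch_with_burst()[4900:5156]
        a = wvd(x, FS)
        b = wvd(3.0 * x, FS)
        np.testing.assert_allclose(b.values, 9.0 * a.values, rtol=1e-9, atol=1e-6)

    def test_frequency_grid_is_half_hz(self):
        tf = wvd(np.zeros(2000), FS)
        assert tf.freqs[1] - tf.freqs[0] == pytest.approx(0.5)
        assert tf.freqs[-1] == pytest.approx(999.5)


class TestSpwvd:
    def test_impulse_windows_reduce_to_wvd(self):
        x = np.cos(2 * np.pi * 100 * np.arange(128) / FS)
        plain = wvd(x, FS)
        windows = SmoothingWindows(np.array([1.0]), np.ones(2 * (128 // 2 + 1) - 1))
        smoothed = spwvd(x, windows, FS, fmin=0, fmax=1000, nfft=128)
        np.testing.assert_allclose(smoothed.values, plain.values, atol=1e-9)

    def test_cross_term_suppression(self):
        t = np.arange(1000) / FS
        x = np.cos(2 * np.pi * 100 * t) + np.cos(2 * np.pi * 300 * t)
        plain = wvd(x, FS)
        smoothed = spwvd(x, SmoothingWindows.default(FS, time_len_s=0.25), FS)

        def cross_mag(tf):
            row = np.argmin(np.abs(tf.freqs - 200.0))
            return np.abs(tf.values[row]).max()

        assert cross_mag(smoothed) < 0.05 * cross_mag(plain)

    def test_tone_row_argmax(self):
        x = np.cos(2 * np.pi * 140 * np.arange(2000) / FS)
        tf = spwvd(x, SmoothingWindows.default(FS), FS, fmin=80, fmax=200)
        row = np.argmax(tf.values.max(axis=1))
        assert abs(tf.freqs[row] - 140) <= 1.0

    def test_zero_signal(self):
        tf = spwvd(np.zeros(2000), None, FS)
        assert not tf.values.any()

    def test_band_restriction_matches_full_matrix(self):
        x = _epoch_with_burst()[4000:6000]
        win = SmoothingWindows.default(FS)
        full = spwvd(x, win, FS)
        band = spwvd(x, win, FS, fmin=80, fmax=200)
        rows = (full.freqs >= 80) & (full.freqs <= 200)
        # the band path uses a direct DFT, the full path an FFT: identical
        # up to floating-point associativity
        np.testing.assert_allclose(band.values, full.values[rows], rtol=1e-9)

    def test_window_longer_than_signal_rejected(self):
        with pytest.raises(ValueError):
            spwvd(np.zeros(100), SmoothingWindows.default(FS), FS)


class TestNormalization:
    @staticmethod
    def _tf(values):
        values = np.atleast_2d(np.asarray(values, dtype=float))
        return TfMatrix(values, np.arange(values.shape[0]) + 100.0,
                        np.arange(values.shape[1], dtype=float), "spwvd")

    def test_row_example(self):
        out = normalize_per_frequency(self._tf([-1.0, 2.0, 4.0]))
        np.testing.assert_allclose(out.values[0], [0.0, 0.5, 1.0])

    def test_all_nonpositive_row_maps_to_zero(self):
        out = normalize_per_frequency(self._tf([-3.0, -1.0, 0.0]))
        assert not out.values.any()

    @settings(derandomize=True, max_examples=50)
    @given(hnp.arrays(np.float64, (4, 6), elements=st.floats(-10, 10)))
    def test_range_idempotence_and_saturation(self, values):
        tf = self._tf(values)
        once = normalize_per_frequency(tf)
        assert once.values.min() >= 0.0 and once.values.max() <= 1.0
        for row, src in zip(once.values, tf.values):
            if (src > 0).any():
                assert row.max() == pytest.approx(1.0)
        twice = normalize_per_frequency(once)
        np.testing.assert_allclose(twice.values, once.values)


def _norm_tf(n_rows=5, n_cols=400, in_window=True):
    """Row-normalized matrix whose row maxima sit inside/outside the window."""
    times = np.arange(n_cols) * 0.5  # 0.5 ms grid, 200 ms span
    freqs = np.linspace(100, 180, n_rows)
    vals = np.full((n_rows, n_cols), 0.2)
    peak_col = n_cols // 2 if in_window else 2
    vals[:, peak_col] = 1.0
    return TfMatrix(vals, freqs, times, "normalized")


class TestCurveC:
    def test_in_window_maxima_give_unit_curve(self):
        curve = curve_c(_norm_tf(in_window=True), RIPPLE, display_ms=100.0)
        np.testing.assert_allclose(curve.values, 1.0)
        assert curve.max_index == 1.0

    def test_off_window_maxima_give_sub_unit_curve(self):
        curve = curve_c(_norm_tf(in_window=False), RIPPLE, display_ms=100.0)
        assert np.all(curve.values < 1.0)
        assert curve.max_index == pytest.approx(0.2)

    def test_single_frequency_band(self):
        tf = _norm_tf(n_rows=1)
        curve = curve_c(tf, RIPPLE, display_ms=100.0)
        assert len(curve.values) == 1

    def test_empty_band_intersection(self):
        tf = _norm_tf()
        with pytest.raises(ValueError):
            curve_c(tf, FAST_RIPPLE)


class TestRenormalizeAndCohort:
    def test_unit_max_index_is_identity(self):
        tf = _norm_tf()
        out = renormalize(tf, CurveC(tf.freqs, tf.values.max(axis=1), 1.0))
        np.testing.assert_allclose(out.values, tf.values)

    def test_half_max_index_doubles_and_clips(self):
        tf = _norm_tf()
        out = renormalize(tf, CurveC(tf.freqs, tf.values.max(axis=1), 0.5))
        np.testing.assert_allclose(out.values, np.clip(tf.values * 2, 0, 1))
        assert out.values.max() == 1.0

    def test_zero_max_index_rejected(self):
        tf = _norm_tf()
        with pytest.raises(DegenerateEpochError):
            renormalize(tf, CurveC(tf.freqs, np.zeros(len(tf.freqs)), 0.0))

    def test_cohort_median_odd_even_single(self):
        mk = lambda m: CurveC(np.array([100.0]), np.array([m]), m)
        assert fit_cohort([mk(0.2), mk(0.5), mk(0.8)]).median_max_index == 0.5
        assert fit_cohort([mk(0.2), mk(0.4), mk(0.6), mk(0.8)]).median_max_index == 0.5
        assert fit_cohort([mk(0.7)]).median_max_index == pytest.approx(0.7)
        with pytest.raises(ValueError):
            fit_cohort([])

    def test_single_event_cohort_equals_renormalized(self):
        tf = normalize_per_frequency(
            spwvd(_epoch_with_burst()[4000:6000], None, FS, fmin=80, fmax=200))
        curve = curve_c(tf, RIPPLE)
        cohort = fit_cohort([curve])
        np.testing.assert_allclose(adjust_aspwvd(tf, cohort).values,
                                   renormalize(tf, curve).values)

    def test_saturation_relative_to_median(self):
        # three epochs with maxima 0.4 / 0.5 / 0.8: dividing by the median
        # saturates the below-median epochs somewhere, not the one above
        tfs, curves = [], []
        for m in (0.4, 0.5, 0.8):
            tf = _norm_tf(in_window=False)
            vals = tf.values * m  # row maxima in window scale to 0.2 * m...
            tf = TfMatrix(np.clip(vals, 0, 1), tf.freqs, tf.times_ms, "normalized")
            tfs.append(tf)
            curves.append(CurveC(tf.freqs, tf.values.max(axis=1), float(tf.values.max())))
        cohort = fit_cohort(curves)
        assert cohort.median_max_index == pytest.approx(0.5)
        adjusted = [adjust_aspwvd(tf, cohort) for tf in tfs]
        assert adjusted[0].values.max() < 1.0  # 0.4 / 0.5 < 1
        assert adjusted[1].values.max() == pytest.approx(1.0)  # exactly the median
        assert adjusted[2].values.max() == 1.0  # clipped
        with pytest.raises(DegenerateCohortError):
            adjust_aspwvd(tfs[0], type(cohort)(0.0, 1))


class TestCropDisplay:
    def test_ripple_span(self):
        tf = spwvd(np.zeros(2000), None, FS)
        out = crop_display(tf, RIPPLE)
        assert out.times_ms[-1] - out.times_ms[0] <= 200.0
        assert len(out.times_ms) == 400
        assert out.freqs[0] >= 80 and out.freqs[-1] <= 200

    def test_fr_span(self):
        tf = spwvd(np.zeros(2000), None, FS)
        out = crop_display(tf, FAST_RIPPLE)
        assert len(out.times_ms) == 200

    def test_idempotence(self):
        tf = spwvd(_epoch_with_burst()[4000:6000], None, FS)
        once = crop_display(tf, RIPPLE)
        twice = crop_display(once, RIPPLE)
        np.testing.assert_array_equal(once.values, twice.values)
        np.testing.assert_array_equal(once.times_ms, twice.times_ms)
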