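"""Detector: filtering, peak extraction, consecutive-peak rules, epochs."""

import numpy as np
import pytest

from hfopipe import DegenerateBaselineError
from hfopipe.detector import (
    FAST_RIPPLE,
    RIPPLE,
    BaselineStats,
    Epoch,
    HfoEvent,
    PeakSeries,
    bandpass_fir,
    baseline_stats,
    detect_events,
    extract_epochs,
    find_peaks,
    sample_balanced,
)
from oracles import brute_force_events, random_peak_series

FS = 2000.0


class TestBandpass:
    def test_passband_tone_preserved(self):
        t = np.arange(20_000) / FS
        tone = np.sin(2 * np.pi * 140 * t)
        out = bandpass_fir(tone, RIPPLE, FS)
        gain = np.max(np.abs(out[5000:15000]))
        assert abs(gain - 1.0) < 0.05

    def test_stopband_tone_attenuated(self):
        t = np.arange(20_000) / FS
        tone = np.sin(2 * np.pi * 30 * t)
        out = bandpass_fir(tone, RIPPLE, FS)
        gain = np.max(np.abs(out[5000:15000]))
        assert 20 * np.log10(1.0 / max(gain, 1e-12)) >= 20

    def test_zero_in_zero_out(self):
        out = bandpass_fir(np.zeros(5000), FAST_RIPPLE, FS)
        assert not out.any()

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            bandpass_fir(np.zeros(5000), FAST_RIPPLE, 800.0)


class TestBaselineStats:
    def test_constant(self):
        s = baseline_stats(np.full(100, 3.5))
        assert s.mean == pytest.approx(3.5) and s.sd == 0

    def test_white_noise_sd(self):
        x = np.random.default_rng(0).standard_normal(600_000)
        assert abs(baseline_stats(x).sd - 1.0) < 0.01

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=1000)
        a = baseline_stats(x)
        b = baseline_stats(rng.permutation(x))
        assert a.mean == pytest.approx(b.mean) and a.sd == pytest.approx(b.sd)


class TestFindPeaks:
    def test_tone_peak_count(self):
        f0, dur = 137.0, 2.0
        t = np.arange(int(dur * FS)) / FS
        peaks = find_peaks(np.sin(2 * np.pi * f0 * t),
                           BaselineStats(0.0, 1.0))
        assert abs(len(peaks.indices) - round(2 * f0 * dur)) <= 1

    def test_monotone_ramp_empty(self):
        peaks = find_peaks(np.arange(100.0))
        assert len(peaks.indices) == 0

    def test_plateau_not_strict_extremum(self):
        x = np.array([0.0, 1, 2, 2, 2, 1, 0])
        peaks = find_peaks(x, BaselineStats(0.0, 1.0))
        assert len(peaks.indices) == 0

    def test_amplitudes_relative_to_baseline_mean(self):
        x = np.array([5.0, 7, 5, 3, 5])
        peaks = find_peaks(x, BaselineStats(5.0, 1.0))
        np.testing.assert_allclose(peaks.amplitudes, [2.0, 2.0])


def _series(amps, spacing=8):
    amps = np.asarray(amps, dtype=float)
    return PeakSeries(np.arange(len(amps)) * spacing + 100, amps)


class TestDetectEvents:
    BASE = BaselineStats(0.0, 1.0)

    def test_strict_count_boundary(self):
        # 8 peaks above 3.5 SD but only 5 above 9 SD -> no ripple (needs 6)
        amps = [10, 10, 10, 10, 10, 4, 4, 4]
        assert detect_events(_series(amps), self.BASE, RIPPLE, FS) == []

    def test_rule_satisfied(self):
        events = detect_events(_series([10] * 8), self.BASE, RIPPLE, FS)
        assert len(events) == 1
        assert events[0].n_peaks == 8
        assert events[0].center_sample == (100 + 100 + 7 * 8) // 2

    def test_overlapping_windows_merge(self):
        events = detect_events(_series([10] * 12), self.BASE, RIPPLE, FS)
        assert len(events) == 1
        assert events[0].n_peaks == 12

    def test_nearby_events_merge_within_100ms(self):
        # two qualifying runs separated by one sub-threshold peak, < 100 ms apart
        amps = [10] * 8 + [0.1] + [10] * 8
        events = detect_events(_series(amps, spacing=8), self.BASE, RIPPLE, FS)
        assert len(events) == 1

    def test_distant_events_stay_separate(self):
        amps = [10] * 8 + [0.1] + [10] * 8
        events = detect_events(_series(amps, spacing=120), self.BASE, RIPPLE, FS)
        assert len(events) == 2

    def test_degenerate_baseline(self):
        with pytest.raises(DegenerateBaselineError):
            detect_events(_series([1.0] * 8), BaselineStats(0.0, 0.0), RIPPLE, FS)

    @pytest.mark.parametrize("band", [RIPPLE, FAST_RIPPLE], ids=lambda b: b.name)
    def test_matches_bruteforce_oracle(self, band):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            peaks = random_peak_series(rng)
            got = detect_events(peaks, self.BASE, band, FS)
            expected = brute_force_events(peaks, self.BASE.sd, band, FS)
            assert len(got) == len(expected)
            for ev, (s, e, center) in zip(got, expected):
                assert ev.center_sample == center
                assert ev.peak_indices[0] == peaks.indices[s]
                assert ev.peak_indices[-1] == peaks.indices[e]

    def test_amplitude_monotonicity(self):
        # scaling amplitudes up (baseline fixed) never removes an event
        rng = np.random.default_rng(7)
        for _ in range(25):
            peaks = random_peak_series(rng)
            before = detect_events(peaks, self.BASE, RIPPLE, FS)
            louder = PeakSeries(peaks.indices, peaks.amplitudes * 2.0)
            after = detect_events(louder, self.BASE, RIPPLE, FS)
            for ev in before:
                assert any(new.peak_indices[0] <= ev.center_sample
                           <= new.peak_indices[-1] for new in after)


class TestEpochs:
    def test_event_at_edge_guard_starts_at_zero(self):
        data = np.arange(30_000.0)
        ev = HfoEvent(0, 5000, "ripple")
        (epoch,) = extract_epochs([ev], data, FS)
        assert len(epoch.samples) == 10_000
        assert epoch.samples[0] == 0.0

    def test_event_too_close_to_edge_skipped(self):
        data = np.zeros(30_000)
        assert extract_epochs([HfoEvent(0, 2000, "ripple")], data, FS) == []

    def test_center_alignment(self):
        data = np.zeros(30_000)
        data[12_345] = 99.0
        (epoch,) = extract_epochs([HfoEvent(0, 12_345, "ripple")], data, FS)
        assert epoch.samples[5000] == 99.0


class TestSampleBalanced:
    @staticmethod
    def _epochs(n0, n1):
        return ([Epoch(np.zeros(4), "ripple", 0, HfoEvent(0, i, "ripple"))
                 for i in range(n0)]
                + [Epoch(np.zeros(4), "ripple", 1, HfoEvent(0, i, "ripple"))
                   for i in range(n1)])

    def test_exact_balance(self):
        out = sample_balanced(self._epochs(10, 10), 10, seed=0)
        labels = [e.label for e in out]
        assert labels.count(0) == labels.count(1) == 10

    def test_deficient_class_named(self):
        with pytest.raises(ValueError, match="class 0"):
            sample_balanced(self._epochs(5, 10), 6, seed=0)

    def test_seeded_determinism(self):
        eps = self._epochs(20, 20)
        a = sample_balanced(eps, 8, seed=3)
        b = sample_balanced(eps, 8, seed=3)
        assert [e.event.center_sample for e in a] == [e.event.center_sample for e in b]
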