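"""Ripple / fast-ripple detection by consecutive-peak amplitude rules.

A band-filtered channel is reduced to its strict local extrema; a ripple
is any window of eight consecutive extrema whose absolute amplitudes all
exceed 3.5 SD of the filtered baseline, of which at least six exceed
9 SD.  Fast ripples use 3 SD for all eight peaks with at least four
above 10.5 SD.  Overlapping qualifying windows merge into a single
event.  Candidate events whose raw neighborhood is dominated by a lone
sharp transient (filter ringing, not a genuine oscillation) are dropped,
and 5 s raw epochs centered on the surviving events are extracted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import filtfilt, firwin

from ._errors import DegenerateBaselineError

__all__ = [
    "PeakRule",
    "BandSpec",
    "RIPPLE",
    "FAST_RIPPLE",
    "BANDS",
    "PeakSeries",
    "BaselineStats",
    "HfoEvent",
    "Epoch",
    "bandpass_fir",
    "baseline_stats",
    "find_peaks",
    "detect_events",
    "reject_false_hfos",
    "detect_channel",
    "extract_epochs",
    "sample_balanced",
]

logger = logging.getLogger(__name__)

EPOCH_S = 5.0
MERGE_GAP_S = 0.1


@dataclass(frozen=True)
class PeakRule:
    """Consecutive-peak thresholds, in multiples of the baseline SD."""

    n_consec: int
    all_thresh_sd: float
    strict_count: int
    strict_thresh_sd: float


@dataclass(frozen=True)
class BandSpec:
    name: str
    low: float
    high: float
    fir_len: int
    rule: PeakRule

    def display_ms(self) -> float:
        """Width of the rendering window centered on an event."""
        return 200.0 if self.name == "ripple" else 100.0


RIPPLE = BandSpec("ripple", 80.0, 200.0, 330, PeakRule(8, 3.5, 6, 9.0))
FAST_RIPPLE = BandSpec("fr", 200.0, 500.0, 132, PeakRule(8, 3.0, 4, 10.5))
BANDS = {"ripple": RIPPLE, "fr": FAST_RIPPLE}


@dataclass
class BaselineStats:
    mean: float
    sd: float


@dataclass
class PeakSeries:
    """Strict local extrema of a filtered trace.

    ``amplitudes`` are absolute deviations from the baseline mean, so the
    SD thresholds apply symmetrically to maxima and minima.
    """

    indices: np.ndarray  # sample indices, strictly increasing
    amplitudes: np.ndarray  # |value - baseline mean|, µV


@dataclass
class HfoEvent:
    channel: int
    center_sample: int
    band: str
    label: int | None = None  # 0 = EZ, 1 = non-EZ, None = unlabeled
    peak_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def n_peaks(self) -> int:
        return len(self.peak_indices)


@dataclass
class Epoch:
    """Raw 5 s window of the original signal centered on an event."""

    samples: np.ndarray
    band: str
    label: int | None
    event: HfoEvent


def bandpass_fir(signal: np.ndarray, band: BandSpec, fs: float) -> np.ndarray:
    """Zero-phase Hamming-window FIR band-pass of the stated tap count.

    The filter is applied forward and backward (``filtfilt``) so that
    event centers stay aligned between the raw and filtered traces.
    """
    if band.high >= fs / 2:
        raise ValueError("band edge at or above Nyquist")
    if len(signal) <= 3 * band.fir_len:
        raise ValueError("signal shorter than filter transient")
    taps = firwin(band.fir_len, [band.low, band.high], pass_zero=False,
                  window="hamming", fs=fs)
    return filtfilt(taps, 1.0, signal)


def baseline_stats(filtered: np.ndarray) -> BaselineStats:
    """Mean and SD of the whole filtered segment (the baseline window)."""
    if len(filtered) == 0:
        raise ValueError("empty signal")
    return BaselineStats(float(np.mean(filtered)), float(np.std(filtered)))


def find_peaks(filtered: np.ndarray, baseline: BaselineStats | None = None) -> PeakSeries:
    """All strict local maxima and minima of the filtered trace.

    Plateau samples are not extrema (strict inequality against both
    neighbors).  Amplitudes are measured from the baseline mean.
    """
    if baseline is None:
        baseline = baseline_stats(filtered)
    x = np.asarray(filtered, dtype=float)
    if len(x) < 3:
        return PeakSeries(np.array([], dtype=int), np.array([]))
    interior = x[1:-1]
    is_max = (interior > x[:-2]) & (interior > x[2:])
    is_min = (interior < x[:-2]) & (interior < x[2:])
    idx = np.flatnonzero(is_max | is_min) + 1
    return PeakSeries(idx, np.abs(x[idx] - baseline.mean))


def detect_events(peaks: PeakSeries, baseline: BaselineStats, band: BandSpec,
                  fs: float = 2000.0, channel: int = 0) -> list[HfoEvent]:
    """Scan every window of ``n_consec`` adjacent peaks against the rule.

    A window qualifies when all of its peaks exceed ``all_thresh_sd`` SD
    and at least ``strict_count`` of them exceed ``strict_thresh_sd`` SD.
    Overlapping qualifying windows merge into one event, as do events
    whose contributing peaks lie closer than 100 ms; the event center is
    the midpoint of the first and last contributing peak.
    """
    rule = band.rule
    n = len(peaks.indices)
    if baseline.sd == 0:
        if np.any(peaks.amplitudes > 0):
            raise DegenerateBaselineError("baseline SD is zero but peaks are nonzero")
        return []
    if n < rule.n_consec:
        return []
    above = peaks.amplitudes > rule.all_thresh_sd * baseline.sd
    strict = peaks.amplitudes > rule.strict_thresh_sd * baseline.sd
    w = rule.n_consec
    above_run = np.convolve(above.astype(int), np.ones(w, dtype=int), "valid") == w
    strict_sum = np.convolve(strict.astype(int), np.ones(w, dtype=int), "valid")
    starts = np.flatnonzero(above_run & (strict_sum >= rule.strict_count))
    if starts.size == 0:
        return []
    # merge overlapping windows into peak-index intervals [first, last]
    intervals: list[list[int]] = []
    for s in starts:
        e = s + w - 1
        if intervals and s <= intervals[-1][1]:
            intervals[-1][1] = e
        else:
            intervals.append([s, e])
    # merge events whose contributing peaks are closer than 100 ms
    merge_gap = MERGE_GAP_S * fs
    merged: list[list[int]] = []
    for first, last in intervals:
        if merged and peaks.indices[first] - peaks.indices[merged[-1][1]] < merge_gap:
            merged[-1][1] = last
        else:
            merged.append([first, last])
    events = []
    for first, last in merged:
        contrib = peaks.indices[first : last + 1]
        center = int((contrib[0] + contrib[-1]) // 2)
        events.append(HfoEvent(channel, center, band.name,
                               peak_indices=contrib.copy()))
    return events


def reject_false_hfos(events: list[HfoEvent], raw: np.ndarray, band: BandSpec,
                      fs: float = 2000.0) -> list[HfoEvent]:
    """Drop candidates produced by filter ringing of sharp transients.

    A genuine oscillation keeps oscillating in the *raw* trace: around
    its largest raw deflection there are several alternating extrema of
    comparable size.  Filtering a lone spike instead yields ringing whose
    raw neighborhood holds a single biphasic deflection.  An event is
    rejected when the dominant raw deflection within ±100 ms of its
    center exceeds 6x the raw channel SD and fewer than 4 strict raw
    extrema within ±25 ms of that deflection reach half its amplitude.
    """
    if not events:
        return []
    raw = np.asarray(raw, dtype=float)
    mean = float(np.mean(raw))
    sd = float(np.std(raw))
    near = int(round(0.1 * fs))
    close = int(round(0.025 * fs))
    kept = []
    for ev in events:
        s0 = max(ev.center_sample - near, 0)
        s1 = min(ev.center_sample + near + 1, len(raw))
        seg = np.abs(raw[s0:s1] - mean)
        peak_rel = int(np.argmax(seg))
        peak_val = seg[peak_rel]
        if peak_val <= 6.0 * sd:
            kept.append(ev)
            continue
        p = s0 + peak_rel
        w0 = max(p - close, 1)
        w1 = min(p + close + 1, len(raw) - 1)
        win = raw[w0:w1]
        prev = raw[w0 - 1 : w1 - 1]
        nxt = raw[w0 + 1 : w1 + 1]
        extrema = ((win > prev) & (win > nxt)) | ((win < prev) & (win < nxt))
        big = np.abs(win - mean) >= 0.5 * peak_val
        if int(np.count_nonzero(extrema & big)) >= 4:
            kept.append(ev)
    return kept


def detect_channel(raw: np.ndarray, band: BandSpec, fs: float = 2000.0,
                   channel: int = 0, reject_false: bool = True) -> list[HfoEvent]:
    """Full single-channel detection: filter, peaks, rule scan, rejection."""
    filtered = bandpass_fir(raw, band, fs)
    stats = baseline_stats(filtered)
    peaks = find_peaks(filtered, stats)
    events = detect_events(peaks, stats, band, fs, channel=channel)
    if reject_false:
        events = reject_false_hfos(events, raw, band, fs)
    return events


def extract_epochs(events: list[HfoEvent], data: np.ndarray,
                   fs: float = 2000.0) -> list[Epoch]:
    """Cut 5 s raw epochs centered on each event.

    ``data`` is the raw channels x samples matrix (a 1-D array is treated
    as a single channel).  Events closer than 2.5 s to either edge are
    skipped with a warning.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    n_epoch = int(round(EPOCH_S * fs))
    half = n_epoch // 2
    epochs = []
    for ev in events:
        start = ev.center_sample - half
        stop = start + n_epoch
        if start < 0 or stop > data.shape[1]:
            logger.warning("event at sample %d too close to edge; skipped",
                           ev.center_sample)
            continue
        epochs.append(Epoch(data[ev.channel, start:stop].copy(), ev.band,
                            ev.label, ev))
    return epochs


def sample_balanced(epochs: list[Epoch], n_per_class: int, seed: int) -> list[Epoch]:
    """Draw exactly ``n_per_class`` epochs per class without replacement."""
    by_class = {0: [], 1: []}
    for ep in epochs:
        if ep.label in by_class:
            by_class[ep.label].append(ep)
    for cls, pool in by_class.items():
        if len(pool) < n_per_class:
            raise ValueError(
                f"class {cls} has only {len(pool)} epochs, need {n_per_class}"
            )
    rng = np.random.default_rng(seed)
    chosen = []
    for cls in (0, 1):
        pool = by_class[cls]
        idx = rng.choice(len(pool), size=n_per_class, replace=False)
        chosen.extend(pool[i] for i in idx)
    order = rng.permutation(len(chosen))
    return [chosen[i] for i in order]
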