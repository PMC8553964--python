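"""Independent brute-force oracles used to cross-check the detector."""

import numpy as np

from hfopipe.detector import BandSpec, PeakSeries


def brute_force_events(peaks: PeakSeries, sd: float, band: BandSpec,
                       fs: float = 2000.0):
    """Enumerate every length-8 peak window and merge qualifying ones.

    Returns a list of ``(first_peak_pos, last_peak_pos, center_sample)``
    tuples using positions into the peak series.  Deliberately naive:
    explicit loops, no vectorization shared with the implementation.
    """
    rule = band.rule
    amps = peaks.amplitudes
    idx = peaks.indices
    n = len(idx)
    wins = []
    for i in range(n - rule.n_consec + 1):
        window = amps[i : i + rule.n_consec]
        if all(a > rule.all_thresh_sd * sd for a in window):
            n_strict = sum(a > rule.strict_thresh_sd * sd for a in window)
            if n_strict >= rule.strict_count:
                wins.append((i, i + rule.n_consec - 1))
    merged = []
    for s, e in wins:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    events = []
    for s, e in merged:
        if events and idx[s] - idx[events[-1][1]] < 0.1 * fs:
            events[-1] = (events[-1][0], e)
        else:
            events.append((s, e))
    return [(s, e, int((idx[s] + idx[e]) // 2)) for s, e in events]


def random_peak_series(rng: np.random.Generator, n: int = 120,
                       sd: float = 1.0) -> PeakSeries:
    """Peak series with a mixture of baseline and burst-like amplitudes."""
    indices = np.cumsum(rng.integers(3, 12, size=n))
    amps = np.abs(rng.normal(0, 2 * sd, size=n))
    for _ in range(rng.integers(1, 5)):
        start = int(rng.integers(0, max(n - 12, 1)))
        length = int(rng.integers(4, 14))
        amps[start : start + length] = rng.uniform(2, 14, size=min(length, n - start)) * sd
    return PeakSeries(indices, amps)
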