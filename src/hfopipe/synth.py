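"""Seeded synthetic intracranial EEG with ground-truth high-frequency events.

The generator emulates the acquisition conditions this pipeline targets:
2,000 Hz multichannel recordings whose background is 1/f ("pink") noise,
with Gaussian-windowed oscillation bursts implanted in the ripple
(80-200 Hz) and fast-ripple (200-500 Hz) bands and optional interictal
spike-like sharp transients.  Epileptogenic (label 0) and
non-epileptogenic (label 1) events share their frequency and duration
distributions and differ only in their burst-amplitude distribution,
which is the separability knob the downstream classifier is expected to
exploit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._errors import AliasingError, PlacementError
from .io_montage import Recording

__all__ = [
    "SimConfig",
    "SimEvent",
    "GroundTruth",
    "make_background",
    "make_hfo_kernel",
    "make_spike",
    "simulate_recording",
    "EZ",
    "NON_EZ",
]

EZ = 0
NON_EZ = 1

RIPPLE_BAND = (80.0, 200.0)
FR_BAND = (200.0, 500.0)

#: Events must sit this far from the recording edges so a 5 s epoch fits.
EDGE_GUARD_S = 2.5
#: Minimum separation between implanted items, keeping epochs single-event.
MIN_GAP_S = 0.5


@dataclass(frozen=True)
class SimConfig:
    """Synthetic recording parameters.

    Rates are events per minute per channel.  Amplitudes are the peak of
    the burst envelope in µV; ``noise_scale`` is the standard deviation of
    the pink-noise background in µV.
    """

    duration_s: float = 300.0
    fs: float = 2000.0
    n_channels: int = 1
    ripple_rate: float = 6.0
    fr_rate: float = 0.0
    ez_amp_mean: float = 60.0
    nonez_amp_mean: float = 30.0
    amp_sd: float = 10.0
    freq_range_ripple: tuple[float, float] = (100.0, 180.0)
    freq_range_fr: tuple[float, float] = (250.0, 400.0)
    burst_cycles: tuple[int, int] = (6, 10)
    spike_rate: float = 0.0
    spike_amp_mean: float = 200.0
    spike_width_ms: tuple[float, float] = (20.0, 40.0)
    noise_scale: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.duration_s <= 0 or self.fs <= 0:
            raise ValueError("duration_s and fs must be positive")
        if self.n_channels < 1:
            raise ValueError("need at least one channel")
        for name in ("ripple_rate", "fr_rate", "spike_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.freq_range_ripple
        if not (RIPPLE_BAND[0] <= lo < hi <= RIPPLE_BAND[1]):
            raise ValueError("freq_range_ripple must lie inside 80-200 Hz")
        lo, hi = self.freq_range_fr
        if not (FR_BAND[0] <= lo < hi <= FR_BAND[1]):
            raise ValueError("freq_range_fr must lie inside 200-500 Hz")
        if self.burst_cycles[0] < 4:
            raise ValueError("bursts need >= 4 cycles (8 oscillation peaks)")


@dataclass(frozen=True)
class SimEvent:
    """One implanted oscillation burst."""

    channel: int
    center_sample: int
    band: str  # "ripple" | "fr"
    label: int  # 0 = EZ, 1 = non-EZ
    amp_uv: float
    freq_hz: float


@dataclass
class GroundTruth:
    """Every implanted event and spike, in placement order per channel."""

    events: list[SimEvent] = field(default_factory=list)
    spikes: list[tuple[int, int]] = field(default_factory=list)  # (channel, center)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "channel": e.channel,
                    "center_sample": e.center_sample,
                    "band": e.band,
                    "label": e.label,
                    "amp_uv": e.amp_uv,
                    "freq_hz": e.freq_hz,
                }
                for e in self.events
            ],
            columns=["channel", "center_sample", "band", "label", "amp_uv", "freq_hz"],
        )


def make_background(duration_s: float, fs: float, noise_scale: float,
                    seed=None) -> np.ndarray:
    """Pink (1/f amplitude spectrum) Gaussian noise.

    Synthesized by spectral shaping of white Gaussian noise and rescaled
    so that the output standard deviation equals ``noise_scale`` exactly;
    the mean is zero by construction (zero DC component).
    """
    if duration_s <= 0 or fs <= 0:
        raise ValueError("duration_s and fs must be positive")
    n = int(round(duration_s * fs))
    if noise_scale == 0:
        return np.zeros(n)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.zeros_like(freqs)
    shape[1:] = 1.0 / np.sqrt(freqs[1:])
    x = np.fft.irfft(spec * shape, n=n)
    sd = x.std()
    if sd > 0:
        x *= noise_scale / sd
    return x


def make_hfo_kernel(freq_hz: float, n_cycles: float, peak_amp: float,
                    fs: float = 2000.0, phase: float = 0.0) -> np.ndarray:
    """Gaussian-windowed sinusoid with peak absolute amplitude ``peak_amp``.

    The core duration is ``n_cycles / freq_hz``; the Gaussian envelope
    (sigma = duration / 3, a deliberately flat-topped taper so that the
    central oscillation peaks stay near full amplitude) extends the
    snippet beyond the core on both sides.
    """
    if freq_hz >= fs / 2:
        raise AliasingError(f"{freq_hz} Hz is at or above Nyquist ({fs / 2} Hz)")
    if not (80.0 <= freq_hz <= 500.0):
        raise ValueError("burst frequency must lie in 80-500 Hz")
    if n_cycles < 4:
        raise ValueError("bursts need >= 4 cycles")
    duration = n_cycles / freq_hz
    sigma = duration / 3.0
    half = duration / 2.0 + 1.5 * sigma
    n_half = int(round(half * fs))
    t = np.arange(-n_half, n_half + 1) / fs
    snippet = np.exp(-(t**2) / (2 * sigma**2)) * np.cos(2 * np.pi * freq_hz * t + phase)
    peak = np.max(np.abs(snippet))
    if peak > 0 and peak_amp != 0:
        snippet *= peak_amp / peak
    else:
        snippet = np.zeros_like(snippet)
    return snippet


def make_spike(peak_amp: float, width_ms: float, fs: float = 2000.0) -> np.ndarray:
    """Biphasic sharp transient (derivative-of-Gaussian shape).

    ``width_ms`` is the total duration of the transient (the snippet spans
    ±3 sigma with sigma = width / 6).  The waveform has one positive and
    one negative lobe and a single interior zero crossing, i.e. no
    sustained oscillation.
    """
    if not (20.0 <= width_ms <= 200.0):
        raise ValueError("spike width must lie in [20, 200] ms")
    sigma = width_ms / 1000.0 / 6.0
    n_half = int(round(3 * sigma * fs))
    t = np.arange(-n_half, n_half + 1) / fs
    snippet = -t * np.exp(-(t**2) / (2 * sigma**2))
    peak = np.max(np.abs(snippet))
    if peak > 0 and peak_amp != 0:
        snippet *= peak_amp / peak
    else:
        snippet = np.zeros_like(snippet)
    return snippet


def _place_centers(rng: np.random.Generator, n_items: int, n_samples: int,
                   fs: float, occupied: list[int]) -> list[int]:
    """Draw event centers uniformly, rejecting overlaps closer than 0.5 s."""
    lo = int(np.ceil(EDGE_GUARD_S * fs))
    hi = n_samples - lo
    if hi <= lo and n_items > 0:
        raise PlacementError("recording too short for edge-guarded events")
    min_gap = int(round(MIN_GAP_S * fs))
    centers: list[int] = []
    attempts = 0
    max_attempts = 200 * max(n_items, 1)
    taken = list(occupied)
    while len(centers) < n_items:
        if attempts >= max_attempts:
            raise PlacementError(
                f"could not place {n_items} events with {MIN_GAP_S} s spacing"
            )
        attempts += 1
        c = int(rng.integers(lo, hi))
        if all(abs(c - o) >= min_gap for o in taken):
            centers.append(c)
            taken.append(c)
    return centers


def _add_at(signal: np.ndarray, snippet: np.ndarray, center: int) -> None:
    half = len(snippet) // 2
    start = center - half
    stop = start + len(snippet)
    s0, s1 = max(start, 0), min(stop, len(signal))
    signal[s0:s1] += snippet[s0 - start : s1 - start]


def simulate_recording(config: SimConfig):
    """Generate a recording plus the ground truth of every implant.

    Event counts per channel and band are Poisson with mean
    ``rate * duration / 60``; EZ / non-EZ labels are assigned with equal
    probability and amplitudes drawn from the class's normal distribution
    (truncated below at 1 µV).  Returns ``(Recording, GroundTruth)``.
    """
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration_s * config.fs))
    data = np.empty((config.n_channels, n))
    truth = GroundTruth()
    minutes = config.duration_s / 60.0
    for ch in range(config.n_channels):
        sig = make_background(config.duration_s, config.fs, config.noise_scale, rng)
        n_rip = rng.poisson(config.ripple_rate * minutes)
        n_fr = rng.poisson(config.fr_rate * minutes)
        n_spk = rng.poisson(config.spike_rate * minutes)
        occupied: list[int] = []
        for band, count, frange in (
            ("ripple", n_rip, config.freq_range_ripple),
            ("fr", n_fr, config.freq_range_fr),
        ):
            centers = _place_centers(rng, count, n, config.fs, occupied)
            occupied.extend(centers)
            for c in centers:
                label = int(rng.integers(0, 2))
                mean = config.ez_amp_mean if label == EZ else config.nonez_amp_mean
                amp = max(float(rng.normal(mean, config.amp_sd)), 1.0)
                freq = float(rng.uniform(*frange))
                cycles = int(rng.integers(config.burst_cycles[0],
                                          config.burst_cycles[1] + 1))
                phase = float(rng.uniform(0, 2 * np.pi))
                _add_at(sig, make_hfo_kernel(freq, cycles, amp, config.fs, phase), c)
                truth.events.append(SimEvent(ch, c, band, label, amp, freq))
        spike_centers = _place_centers(rng, n_spk, n, config.fs, occupied)
        for c in spike_centers:
            amp = float(rng.normal(config.spike_amp_mean, 0.1 * config.spike_amp_mean))
            width = float(rng.uniform(*config.spike_width_ms))
            _add_at(sig, make_spike(amp, width, config.fs), c)
            truth.spikes.append((ch, c))
        data[ch] = sig
    labels = [f"SIM{ch + 1}" for ch in range(config.n_channels)]
    return Recording(data, config.fs, labels), truth
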