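"""Feature transformations: waveform renders, Morlet scalogram, and the
(adjusted) smoothed pseudo Wigner-Ville distribution.

Every detected event is carried as a 5 s raw epoch; all transformations
look at its central portion.  Waveform features keep a 200 ms (ripple)
or 100 ms (fast ripple) slice and attach amplitude limits that are
either *fixed* (absolute µV / µV² bounds, amplitude-preserving) or
*fitted* (the per-epoch maximum, amplitude-invariant).

Time-frequency features are computed on the central 1,000 ms window.
The Wigner-Ville distribution (WVD) of the analytic signal z(t),

    W(t, f) = ∫ z(t + τ/2) z*(t - τ/2) e^{-j2πfτ} dτ,

is evaluated on a 0.5 Hz grid up to 1,000 Hz.  The smoothed pseudo WVD
(SPWVD) applies two independent Kaiser windows: a lag-domain taper ``h``
(whose Fourier transform smooths along frequency) and a time-domain
window ``g`` that averages neighbouring instants.  The SPWVD is then
normalized per frequency row (the "SPWVD index", in [0, 1]), from which
two display variants derive: the *re-normalized* SPWVD divides an epoch
by its own maximum index inside the analysis band and display window,
while the *adjusted* SPWVD (ASPWVD) divides every epoch of a cohort by
the cohort median of those maxima, so that between-epoch energy
differences survive into the image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve, hilbert

from ._errors import DegenerateCohortError, DegenerateEpochError
from .detector import BandSpec, bandpass_fir

__all__ = [
    "RenderSpec",
    "TfMatrix",
    "SmoothingWindows",
    "CurveC",
    "CohortNormalizer",
    "FIXED_ORIGINAL_UV",
    "FIXED_FILTERED_UV",
    "FIXED_WAVELET_UV2",
    "render_original",
    "render_filtered",
    "morlet_scalogram",
    "wvd",
    "spwvd",
    "normalize_per_frequency",
    "curve_c",
    "renormalize",
    "fit_cohort",
    "adjust_aspwvd",
    "crop_display",
]

#: Fixed amplitude limit for original-waveform renders, ±µV (both bands).
FIXED_ORIGINAL_UV = 1000.0
#: Fixed amplitude limits for filtered-waveform renders, ±µV.
FIXED_FILTERED_UV = {"ripple": 50.0, "fr": 10.0}
#: Fixed energy limits for wavelet-spectrum renders, µV².
FIXED_WAVELET_UV2 = {"ripple": 1000.0, "fr": 10.0}

#: Fallback fitted limit when an epoch slice is identically zero.
ZERO_SLICE_ALPHA = 1.0

TF_WINDOW_S = 1.0  # analysis window for time-frequency transforms
TF_GRID_HZ = 0.5  # SPWVD frequency step
TF_FMAX_HZ = 1000.0


@dataclass(frozen=True)
class RenderSpec:
    """Scale mode plus the resolved amplitude/energy limits of a render.

    ``fitted_alpha`` is the per-epoch maximum and is present exactly when
    ``scale_mode == "fitted"``.
    """

    scale_mode: str  # "fixed" | "fitted"
    limits: tuple[float, float]
    fitted_alpha: float | None = None

    def __post_init__(self):
        if self.scale_mode not in ("fixed", "fitted"):
            raise ValueError("scale_mode must be 'fixed' or 'fitted'")
        if (self.fitted_alpha is not None) != (self.scale_mode == "fitted"):
            raise ValueError("fitted_alpha present iff scale_mode='fitted'")


@dataclass
class TfMatrix:
    """Time-frequency matrix with explicit axes.

    ``values`` is frequencies x time; ``freqs`` in Hz and ``times_ms`` in
    milliseconds are strictly increasing.
    """

    values: np.ndarray
    freqs: np.ndarray
    times_ms: np.ndarray
    method: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        if self.values.shape != (len(self.freqs), len(self.times_ms)):
            raise ValueError("values shape must be (n_freqs, n_times)")
        if len(self.freqs) > 1 and not np.all(np.diff(self.freqs) > 0):
            raise ValueError("freq axis must be strictly increasing")
        if len(self.times_ms) > 1 and not np.all(np.diff(self.times_ms) > 0):
            raise ValueError("time axis must be strictly increasing")


@dataclass
class SmoothingWindows:
    """Independent SPWVD smoothing windows.

    ``g`` is the time-domain window (Kaiser, 1,000 ms support at 2 kHz by
    default).  ``h`` is the lag-domain taper whose Fourier transform is
    the frequency-domain smoothing window H(f); shortening ``h`` widens
    the frequency smoothing.  Both are real, nonnegative and
    peak-normalized.
    """

    g: np.ndarray
    h: np.ndarray
    kaiser_beta: float = 14.0

    def __post_init__(self):
        self.g = np.asarray(self.g, dtype=float)
        self.h = np.asarray(self.h, dtype=float)
        for name, w in (("g", self.g), ("h", self.h)):
            if w.ndim != 1 or w.size == 0:
                raise ValueError(f"{name} must be a nonempty 1-D window")
            if np.any(w < 0):
                raise ValueError(f"{name} must be nonnegative")
        self.g = self.g / self.g.max()
        self.h = self.h / self.h.max()
        if self.h.size % 2 == 0:
            raise ValueError("lag window h must have odd length")

    @classmethod
    def default(cls, fs: float = 2000.0, time_len_s: float = TF_WINDOW_S,
                beta: float = 14.0, h_len: int = 127) -> "SmoothingWindows":
        g = np.kaiser(int(round(time_len_s * fs)), beta)
        h = np.kaiser(h_len, beta)
        return cls(g, h, kaiser_beta=beta)


@dataclass
class CurveC:
    """Per-frequency maxima of the SPWVD index inside the display window."""

    freqs: np.ndarray
    values: np.ndarray
    max_index: float

    def __post_init__(self):
        if len(self.freqs) != len(self.values):
            raise ValueError("freqs and values must align")


@dataclass(frozen=True)
class CohortNormalizer:
    """Median of the per-epoch maximum SPWVD indexes over a cohort."""

    median_max_index: float
    n_events: int = 1


def _central_slice(x: np.ndarray, n_keep: int) -> np.ndarray:
    start = (len(x) - n_keep) // 2
    return x[start : start + n_keep]


def _display_samples(band_name: str, fs: float) -> int:
    ms = 200.0 if band_name == "ripple" else 100.0
    return int(round(ms / 1000.0 * fs))


def _waveform_render(trace: np.ndarray, fixed_limit: float, scale: str):
    if scale == "fixed":
        return trace, RenderSpec("fixed", (-fixed_limit, fixed_limit))
    alpha = float(np.max(np.abs(trace)))
    if alpha == 0:
        alpha = ZERO_SLICE_ALPHA
    return trace, RenderSpec("fitted", (-alpha, alpha), fitted_alpha=alpha)


def render_original(epoch: np.ndarray, band: BandSpec, scale: str = "fixed"):
    """Central 200 ms (ripple) / 100 ms (fr) raw slice plus limits.

    Fixed scale uses ±1,000 µV; fitted scale uses ±α with α the maximum
    absolute value of the slice (1 µV fallback for an all-zero slice).
    Returns ``(trace, RenderSpec)``; clipping to the limits happens at
    rasterization.
    """
    epoch = np.asarray(epoch, dtype=float)
    fs = len(epoch) / 5.0  # epochs are 5 s by contract
    trace = _central_slice(epoch, _display_samples(band.name, fs))
    return _waveform_render(trace, FIXED_ORIGINAL_UV, scale)


def render_filtered(epoch: np.ndarray, band: BandSpec, scale: str = "fixed",
                    fs: float = 2000.0):
    """Band-pass the epoch, then slice and scale like ``render_original``.

    Fixed limits are ±50 µV (ripple) and ±10 µV (fast ripple).
    """
    filtered = bandpass_fir(np.asarray(epoch, dtype=float), band, fs)
    trace = _central_slice(filtered, _display_samples(band.name, fs))
    return _waveform_render(trace, FIXED_FILTERED_UV[band.name], scale)


def morlet_scalogram(epoch: np.ndarray, band: BandSpec, fs: float = 2000.0,
                     omega0: float = 8.0) -> TfMatrix:
    """Morlet scalogram (energy, µV²) of the epoch's central second.

    The wavelet is the analytic Morlet with nondimensional center
    frequency ω₀ = 8, evaluated at 1 Hz steps across the band.  The
    transform is normalized so that a pure tone of amplitude A µV at a
    grid frequency yields energy A² at that row.  Computing on the full
    1,000 ms window and then cropping to the central 200 ms (ripple) or
    100 ms (fr) keeps boundary effects out of the display window.
    """
    if band.high >= fs / 2:
        raise ValueError("band extends beyond Nyquist")
    epoch = np.asarray(epoch, dtype=float)
    win = _central_slice(epoch, int(round(TF_WINDOW_S * fs)))
    n = len(win)
    freqs = np.arange(band.low, band.high + 0.5, 1.0)
    spec = np.fft.fft(win)
    omega = 2 * np.pi * np.fft.fftfreq(n, d=1.0 / fs)
    sigma_t = omega0 / (2 * np.pi * freqs)  # seconds, per target frequency
    # analytic Gaussian passband centered on each target frequency;
    # gain 2 on positive frequencies recovers the tone amplitude
    gauss = np.exp(-0.5 * (sigma_t[:, None] * (omega[None, :] - 2 * np.pi * freqs[:, None])) ** 2)
    gauss[:, omega <= 0] = 0.0
    coefs = np.fft.ifft(spec[None, :] * 2.0 * gauss, axis=1)
    energy = np.abs(coefs) ** 2
    times_ms = np.arange(n) / fs * 1000.0
    full = TfMatrix(energy, freqs, times_ms, method="wavelet")
    return crop_display(full, band)


def _analytic(signal: np.ndarray) -> np.ndarray:
    return hilbert(np.asarray(signal, dtype=float))


def _wvd_kernel(z: np.ndarray, max_lag: int, lag_weights: np.ndarray | None):
    """Instantaneous autocorrelation K[n, m] = z[n+m] z*[n-m], m >= 0."""
    n = len(z)
    t = np.arange(n)[:, None]
    m = np.arange(max_lag)[None, :]
    ip = t + m
    im = t - m
    valid = (ip < n) & (im >= 0)
    kern = np.where(valid, z[np.clip(ip, 0, n - 1)] * np.conj(z[np.clip(im, 0, n - 1)]), 0)
    if lag_weights is not None:
        kern = kern * lag_weights[None, :]
    return kern


def _lag_fft(kern: np.ndarray, nfft: int, k_lo: int, k_hi: int) -> np.ndarray:
    """Real WVD values at frequency bins k_lo..k_hi-1 of an nfft lag grid.

    Uses Hermitian symmetry over the lag axis: W = 2 Re(DFT_m) - K[:, 0].
    A direct complex matmul is used for narrow frequency ranges, a full
    FFT otherwise.
    """
    n_t, max_lag = kern.shape
    n_bins = k_hi - k_lo
    if n_bins <= 512:
        k = np.arange(k_lo, k_hi)
        basis = np.exp(-2j * np.pi * np.outer(np.arange(max_lag), k) / nfft)
        partial = kern @ basis
    else:
        partial = np.fft.fft(kern, n=nfft, axis=1)[:, k_lo:k_hi]
    w = 2.0 * partial.real - kern[:, :1].real
    return w.T  # (freq, time)


def wvd(signal: np.ndarray, fs: float = 2000.0, nfft: int | None = None) -> TfMatrix:
    """Discrete Wigner-Ville distribution of the analytic signal.

    Frequency bins are ``k * fs / (2 * nfft)`` (the lag kernel uses whole
    lags, doubling the effective frequency scale), giving a 0.5 Hz grid
    up to 1,000 Hz for a 2 kHz, 2,000-sample input.  Summing the matrix
    over all frequency bins recovers ``nfft * |z(t)|²`` exactly.
    """
    z = _analytic(signal)
    n = len(z)
    if nfft is None:
        nfft = n
    max_lag = min(n // 2 + 1, nfft // 2 + 1)
    kern = _wvd_kernel(z, max_lag, None)
    values = _lag_fft(kern, nfft, 0, nfft)
    freqs = np.arange(nfft) * fs / (2 * nfft)
    times_ms = np.arange(n) / fs * 1000.0
    return TfMatrix(values, freqs, times_ms, method="wvd")


def spwvd(signal: np.ndarray, windows: SmoothingWindows | None = None,
          fs: float = 2000.0, fmin: float = 0.0, fmax: float = TF_FMAX_HZ,
          nfft: int | None = None) -> TfMatrix:
    """Smoothed pseudo Wigner-Ville distribution on the 0.5 Hz grid.

    The lag window ``h`` truncates and tapers the instantaneous
    autocorrelation (frequency smoothing); the time window ``g``,
    normalized to unit sum, is convolved along the time axis (time
    smoothing).  With an impulse ``g`` and an all-ones ``h`` covering
    every lag the transform reduces to :func:`wvd`.  Because both the
    smoothing and the later per-row normalization act on each frequency
    row independently, restricting ``fmin``/``fmax`` to an analysis band
    yields exactly the corresponding rows of the full matrix.
    """
    z = _analytic(signal)
    n = len(z)
    if windows is None:
        windows = SmoothingWindows.default(fs)
    if len(windows.g) > n:
        raise ValueError("time smoothing window longer than signal")
    if nfft is None:
        nfft = int(round(fs / (2 * TF_GRID_HZ)))
    half_h = (len(windows.h) - 1) // 2
    max_lag = min(half_h + 1, n // 2 + 1, nfft // 2 + 1)
    lag_weights = windows.h[half_h : half_h + max_lag]
    kern = _wvd_kernel(z, max_lag, lag_weights)
    df = fs / (2 * nfft)
    k_lo = int(np.ceil(fmin / df - 1e-9))
    k_hi = min(int(np.floor(fmax / df + 1e-9)) + 1, nfft)
    if k_hi <= k_lo:
        raise ValueError("empty frequency range")
    values = _lag_fft(kern, nfft, k_lo, k_hi)
    if len(windows.g) > 1:
        g = windows.g / windows.g.sum()
        values = fftconvolve(values, g[None, :], mode="same", axes=1)
    freqs = np.arange(k_lo, k_hi) * df
    times_ms = np.arange(n) / fs * 1000.0
    return TfMatrix(values, freqs, times_ms, method="spwvd")


def normalize_per_frequency(tf: TfMatrix) -> TfMatrix:
    """Per-row normalization to the SPWVD index.

    Nonpositive entries map to 0; positive entries are divided by their
    frequency row's maximum over time, so every row with any positive
    entry attains 1.  Idempotent.
    """
    vals = tf.values
    row_max = vals.max(axis=1, keepdims=True)
    out = np.zeros_like(vals)
    pos_rows = row_max[:, 0] > 0
    np.divide(vals, row_max, out=out, where=pos_rows[:, None] & (vals > 0))
    return TfMatrix(out, tf.freqs.copy(), tf.times_ms.copy(), method="normalized")


def _window_columns(tf: TfMatrix, window_ms: float) -> np.ndarray:
    center = tf.times_ms.mean()
    return np.abs(tf.times_ms - center) <= window_ms / 2 + 1e-9


def curve_c(tf_norm: TfMatrix, band: BandSpec,
            display_ms: float | None = None) -> CurveC:
    """Per-frequency maxima of the SPWVD index over the display window.

    The window is the central 200 ms (ripple) / 100 ms (fr) of the time
    axis; rows are restricted to the analysis band.  ``max_index`` is the
    maximum of the curve and is < 1 whenever every band row attains its
    global (full-window) maximum outside the display window.
    """
    if display_ms is None:
        display_ms = band.display_ms()
    rows = (tf_norm.freqs >= band.low - 1e-9) & (tf_norm.freqs <= band.high + 1e-9)
    cols = _window_columns(tf_norm, display_ms)
    if not rows.any() or not cols.any():
        raise ValueError("band/display window does not intersect the matrix")
    sub = tf_norm.values[np.ix_(rows, cols)]
    values = sub.max(axis=1)
    return CurveC(tf_norm.freqs[rows].copy(), values, float(values.max()))


def renormalize(tf_norm: TfMatrix, curve: CurveC) -> TfMatrix:
    """Divide an epoch's SPWVD index by its own maximum; clip to [0, 1]."""
    if curve.max_index <= 0:
        raise DegenerateEpochError("curve C maximum is zero")
    vals = np.clip(tf_norm.values / curve.max_index, 0.0, 1.0)
    return TfMatrix(vals, tf_norm.freqs.copy(), tf_norm.times_ms.copy(),
                    method="renormalized")


def fit_cohort(curves: list[CurveC]) -> CohortNormalizer:
    """Median of the maximum SPWVD indexes over a cohort of events.

    An even-sized cohort uses the mean of the two central values.
    """
    if not curves:
        raise ValueError("cohort must contain at least one curve")
    med = float(np.median([c.max_index for c in curves]))
    return CohortNormalizer(med, n_events=len(curves))


def adjust_aspwvd(tf_norm: TfMatrix, normalizer: CohortNormalizer) -> TfMatrix:
    """Adjusted SPWVD: divide by the cohort median maximum; clip to [0, 1].

    Epochs whose own maximum lies below the median keep values < 1;
    epochs above it saturate, so relative energy differences between
    events survive into the image (unlike :func:`renormalize`).
    """
    if normalizer.median_max_index <= 0:
        raise DegenerateCohortError("cohort median maximum index is zero")
    vals = np.clip(tf_norm.values / normalizer.median_max_index, 0.0, 1.0)
    return TfMatrix(vals, tf_norm.freqs.copy(), tf_norm.times_ms.copy(),
                    method="aspwvd")


def crop_display(tf: TfMatrix, band: BandSpec) -> TfMatrix:
    """Central 200 ms (ripple) / 100 ms (fr) columns, band rows only.

    Idempotent: cropping an already cropped matrix returns it unchanged.
    """
    window_ms = band.display_ms()
    rows = (tf.freqs >= band.low - 1e-9) & (tf.freqs <= band.high + 1e-9)
    cols = _window_columns(tf, window_ms)
    if not rows.any() or not cols.any():
        raise ValueError("display window exceeds the matrix span")
    return TfMatrix(tf.values[np.ix_(rows, cols)], tf.freqs[rows],
                    tf.times_ms[cols], method=tf.method)
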