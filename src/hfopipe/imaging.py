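"""Rasterization of feature representations to grayscale images.

Traces and time-frequency matrices are painted onto band-specific native
canvases (ripple 200 x 120, fast ripple 400 x 300, width x height) and
then resized to the 96 x 96 network input with bicubic interpolation.
Intensity polarity is fixed: trace ink / high energy = 1.0 on a 0.0
background.  Rendering is fully deterministic, so identical epochs and
configuration produce bit-identical PNG bytes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image

from .transforms import TfMatrix

__all__ = [
    "GrayImage",
    "NATIVE_SIZE",
    "INPUT_SIZE",
    "rasterize_trace",
    "rasterize_tf",
    "resize_bicubic",
    "save_png",
    "load_png",
]

#: Native canvas (width, height) per band.
NATIVE_SIZE = {"ripple": (200, 120), "fr": (400, 300)}
#: Side length of the square network input.
INPUT_SIZE = 96


@dataclass
class GrayImage:
    """Single-channel raster with intensities in [0, 1]."""

    pixels: np.ndarray  # (height, width)
    band: str
    feature: str | None = None
    scale: str | None = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be 2-D")
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValueError("intensities must lie in [0, 1]")

    @property
    def shape(self):
        return self.pixels.shape


def _value_to_row(values: np.ndarray, lo: float, hi: float, height: int) -> np.ndarray:
    clipped = np.clip(values, lo, hi)
    rows = np.rint((hi - clipped) / (hi - lo) * (height - 1)).astype(int)
    return rows


def rasterize_trace(trace: np.ndarray, limits: tuple[float, float],
                    band: str) -> GrayImage:
    """Draw a waveform as a dark-on-light polyline, no anti-aliasing.

    Values are clipped to ``limits``; +limit maps to the top row.  Each
    canvas column paints the vertical span of the samples that fall into
    it, bridged to the previous column so the polyline is connected.
    """
    lo, hi = limits
    if not (hi > lo):
        raise ValueError("limits must satisfy hi > lo")
    trace = np.asarray(trace, dtype=float)
    if not np.all(np.isfinite(trace)):
        raise ValueError("trace must be finite")
    width, height = NATIVE_SIZE[band]
    canvas = np.zeros((height, width))
    n = len(trace)
    rows = _value_to_row(trace, lo, hi, height)
    cols = np.minimum((np.arange(n) * width) // max(n, 1), width - 1).astype(int)
    prev_row = None
    for c in range(cols.min(), cols.max() + 1):
        in_col = rows[cols == c]
        if in_col.size == 0:
            continue
        r0, r1 = int(in_col.min()), int(in_col.max())
        if prev_row is not None:
            r0, r1 = min(r0, prev_row), max(r1, prev_row)
        canvas[r0 : r1 + 1, c] = 1.0
        prev_row = int(in_col[-1])
    return GrayImage(canvas, band, feature="trace")


def rasterize_tf(tf: TfMatrix, energy_limits: tuple[float, float],
                 band: str) -> GrayImage:
    """Paint a time-frequency matrix with linear intensity mapping.

    Intensity = value mapped from ``[lo, hi]`` to [0, 1] and clipped;
    frequency increases upward and time rightward; cells are resampled
    to the native canvas with nearest-neighbor lookups.
    """
    lo, hi = energy_limits
    if hi <= lo or hi <= 0:
        raise ValueError("energy limit must be positive")
    width, height = NATIVE_SIZE[band]
    vals = np.clip((tf.values - lo) / (hi - lo), 0.0, 1.0)
    nf, nt = vals.shape
    # nearest source cell per canvas pixel; row 0 = highest frequency
    src_rows = np.rint((height - 1 - np.arange(height)) / max(height - 1, 1)
                       * (nf - 1)).astype(int)
    src_cols = np.rint(np.arange(width) / max(width - 1, 1) * (nt - 1)).astype(int)
    canvas = vals[np.ix_(src_rows, src_cols)]
    return GrayImage(canvas, band, feature=tf.method)


def resize_bicubic(img: GrayImage) -> GrayImage:
    """Bicubic resize to the 96 x 96 network input, clipped to [0, 1]."""
    pil = Image.fromarray(img.pixels.astype(np.float32), mode="F")
    small = pil.resize((INPUT_SIZE, INPUT_SIZE), Image.Resampling.BICUBIC)
    pixels = np.clip(np.asarray(small, dtype=float), 0.0, 1.0)
    return GrayImage(pixels, img.band, feature=img.feature, scale=img.scale)


def save_png(img: GrayImage, path) -> None:
    """Write an 8-bit grayscale PNG (intensity 1.0 -> 255)."""
    arr = np.rint(img.pixels * 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path, format="PNG")


def load_png(path, band: str = "ripple") -> GrayImage:
    arr = np.asarray(Image.open(path).convert("L"), dtype=float) / 255.0
    return GrayImage(arr, band)
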