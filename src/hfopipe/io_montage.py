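"""Recording containers, file IO, bipolar montage, and segment screening.

Recordings hold a channels x samples matrix in microvolts.  Two on-disk
formats are supported: EDF (European Data Format, 16-bit) and a plain CSV
dialect with one row per sample and a header of channel labels.  EDF files
are read through MNE; writing uses a self-contained EDF+ -free EDF writer
so that round trips stay within the format's 16-bit quantization.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field, replace
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd

from ._errors import FormatError

__all__ = [
    "Recording",
    "MontageSpec",
    "ScreenReport",
    "read_recording",
    "write_recording",
    "to_bipolar",
    "sequential_pairs",
    "screen_segment",
]


@dataclass
class Recording:
    """Multichannel signal matrix in microvolts.

    Attributes
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal values in µV.
    fs : float
        Sampling rate in Hz.
    channel_labels : list of str
        Unique channel names, one per row of ``data``.
    montage_kind : {"referential", "bipolar"}
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    montage_kind: str = "referential"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("one label per channel required")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if self.montage_kind not in ("referential", "bipolar"):
            raise ValueError(f"unknown montage kind {self.montage_kind!r}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass(frozen=True)
class MontageSpec:
    """Ordered (anode, cathode) label pairs defining a bipolar derivation."""

    pairs: tuple[tuple[str, str], ...]

    def __post_init__(self):
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError("montage pairs must not repeat")


def sequential_pairs(labels: list[str]) -> MontageSpec:
    """Adjacent-contact pairs (1-2, 2-3, ...) in label order."""
    return MontageSpec(tuple(zip(labels[:-1], labels[1:])))


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower()
    if suffix == ".edf":
        return "edf"
    if suffix in (".csv", ".txt"):
        return "csv"
    raise FormatError(f"cannot infer recording format from {path.name!r}")


def read_recording(path, format: str | None = None, *, fs: float | None = None) -> Recording:
    """Read a recording from EDF or delimited text.

    For CSV the sampling rate cannot be stored in the file, so ``fs`` must
    be supplied (default 2000 Hz, the acquisition rate this pipeline
    targets).  EDF values are returned in µV.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    fmt = _infer_format(path, format)
    if fmt == "csv":
        try:
            frame = pd.read_csv(path)
        except Exception as exc:  # pragma: no cover - pandas error variety
            raise FormatError(f"could not parse CSV recording: {exc}") from exc
        if frame.shape[1] == 0 or frame.shape[0] == 0:
            raise FormatError("empty CSV recording")
        data = frame.to_numpy(dtype=float).T
        return Recording(data, fs if fs is not None else 2000.0, list(frame.columns))
    if fmt == "edf":
        import mne

        try:
            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        except Exception as exc:
            raise FormatError(f"could not parse EDF recording: {exc}") from exc
        data = raw.get_data() * 1e6  # volts -> µV
        return Recording(data, float(raw.info["sfreq"]), list(raw.ch_names))
    raise FormatError(f"unsupported format {fmt!r}")


def write_recording(rec: Recording, path, format: str | None = None,
                    physical_max: float | None = None) -> None:
    """Write a recording as CSV or EDF.

    EDF stores int16 samples scaled into a symmetric physical range; the
    default range is the recording's absolute maximum (rounded up), giving
    a quantization step of ``2 * physical_max / 65535`` µV.  Recordings are
    zero-padded to a whole number of 1 s data records.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        frame = pd.DataFrame(rec.data.T, columns=rec.channel_labels)
        frame.to_csv(path, index=False)
        return
    if fmt == "edf":
        _write_edf(rec, path, physical_max)
        return
    raise FormatError(f"unsupported format {fmt!r}")


def _write_edf(rec: Recording, path: Path, physical_max: float | None) -> None:
    if abs(rec.fs - round(rec.fs)) > 1e-9:
        raise FormatError("EDF writer requires an integer sampling rate")
    fs = int(round(rec.fs))
    if physical_max is None:
        peak = float(np.max(np.abs(rec.data))) if rec.data.size else 1.0
        physical_max = max(np.ceil(peak), 1.0)
    pmin, pmax = -float(physical_max), float(physical_max)
    dmin, dmax = -32768, 32767

    n_rec = int(np.ceil(rec.n_samples / fs))
    padded = np.zeros((rec.n_channels, n_rec * fs))
    padded[:, : rec.n_samples] = rec.data

    scale = (dmax - dmin) / (pmax - pmin)
    digital = np.clip(np.rint((padded - pmin) * scale) + dmin, dmin, dmax).astype("<i2")

    ns = rec.n_channels

    def pad(text: str, width: int) -> bytes:
        b = text.encode("ascii")[:width]
        return b + b" " * (width - len(b))

    now = datetime(2000, 1, 1)
    header = b"".join([
        pad("0", 8),
        pad("X X X X", 80),
        pad("Startdate X", 80),
        pad(now.strftime("%d.%m.%y"), 8),
        pad(now.strftime("%H.%M.%S"), 8),
        pad(str(256 * (1 + ns)), 8),
        pad("", 44),
        pad(str(n_rec), 8),
        pad("1", 8),
        pad(str(ns), 4),
    ])
    fields = [
        (16, [lab for lab in rec.channel_labels]),
        (80, ["EEG" for _ in range(ns)]),
        (8, ["uV" for _ in range(ns)]),
        (8, [f"{pmin:.6g}" for _ in range(ns)]),
        (8, [f"{pmax:.6g}" for _ in range(ns)]),
        (8, [str(dmin) for _ in range(ns)]),
        (8, [str(dmax) for _ in range(ns)]),
        (80, ["" for _ in range(ns)]),
        (8, [str(fs) for _ in range(ns)]),
        (32, ["" for _ in range(ns)]),
    ]
    header += b"".join(pad(v, w) for w, values in fields for v in values)

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            block = digital[:, r * fs : (r + 1) * fs]
            fh.write(block.tobytes())


def edf_quantization_step(physical_max: float) -> float:
    """Amplitude resolution of a 16-bit EDF stored with range ±physical_max."""
    return 2.0 * physical_max / 65535.0


def to_bipolar(rec: Recording, montage: MontageSpec) -> Recording:
    """Re-reference to a bipolar montage: output channel = anode - cathode."""
    if rec.montage_kind != "referential":
        raise ValueError("input recording must be referential")
    index = {lab: i for i, lab in enumerate(rec.channel_labels)}
    rows = []
    labels = []
    for anode, cathode in montage.pairs:
        if anode not in index:
            raise KeyError(f"anode channel {anode!r} not in recording")
        if cathode not in index:
            raise KeyError(f"cathode channel {cathode!r} not in recording")
        rows.append(rec.data[index[anode]] - rec.data[index[cathode]])
        labels.append(f"{anode}-{cathode}")
    return Recording(np.array(rows), rec.fs, labels, montage_kind="bipolar")


@dataclass
class ScreenReport:
    """Per-channel sample indices whose deviation exceeds the 6 SD rule."""

    flagged: dict[str, np.ndarray] = field(default_factory=dict)
    segment_samples: int = 0

    @property
    def n_flagged(self) -> int:
        return int(sum(len(v) for v in self.flagged.values()))


def screen_segment(rec: Recording, segment_s: float = 300.0):
    """Screen the leading ``segment_s`` seconds for sharp transients.

    A sample is flagged when its absolute deviation from the channel's
    baseline mean exceeds ``max(6 * SD, 1e-9)`` µV, with the baseline mean
    and SD computed per channel over the whole candidate segment of the
    raw signal.  Returns ``(accepted, report)`` where ``accepted`` is True
    iff no sample on any channel was flagged.
    """
    n_seg = int(round(segment_s * rec.fs))
    if n_seg > rec.n_samples:
        raise ValueError("requested segment is longer than the recording")
    seg = rec.data[:, :n_seg]
    mean = seg.mean(axis=1, keepdims=True)
    sd = seg.std(axis=1, keepdims=True)
    thresh = np.maximum(6.0 * sd, 1e-9)
    report = ScreenReport(segment_samples=n_seg)
    for i, lab in enumerate(rec.channel_labels):
        idx = np.flatnonzero(np.abs(seg[i] - mean[i]) > thresh[i])
        if idx.size:
            report.flagged[lab] = idx
    return report.n_flagged == 0, report
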