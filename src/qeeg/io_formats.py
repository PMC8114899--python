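"""Recording and annotation I/O, plus the core time/unit conventions.

Conventions used throughout the package:

* all times are seconds from recording start;
* intervals are half-open ``[onset, onset + duration)``;
* signals are stored and processed in microvolts (μV);
* power is reported in μV² (band power) or μV²/Hz (PSD).

Signals interchange as plain EDF (16-bit) or CSV; interval annotations
(artifact masks, detected or ground-truth events) as a four-column TSV
``onset_s  duration_s  channel  label``, where channel ``*`` means the
interval applies to every channel.

EDF files are read through MNE; writing uses a minimal EDF encoder
implemented here (one data record per second, symmetric physical range,
16-bit quantization).
"""

from __future__ import annotations

import datetime
import enum
import io
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, InputError

__all__ = [
    "ChannelRole", "ChannelInfo", "SubjectMeta", "Recording",
    "Interval", "AnnotationTrack",
    "read_recording", "write_recording", "read_annotations", "write_annotations",
]


class ChannelRole(str, enum.Enum):
    cortical_left = "cortical_left"
    cortical_right = "cortical_right"
    hippocampal = "hippocampal"
    reference = "reference"
    other = "other"


@dataclass(frozen=True)
class ChannelInfo:
    name: str
    role: ChannelRole = ChannelRole.other


class Genotype(str, enum.Enum):
    WT = "WT"
    AS = "AS"


class AgeGroup(str, enum.Enum):
    p1_5wk = "p1_5wk"
    p2wk = "p2wk"
    p3wk = "p3wk"
    adult = "adult"


class Cycle(str, enum.Enum):
    light = "light"
    dark = "dark"


@dataclass(frozen=True)
class SubjectMeta:
    subject_id: str = "unknown"
    genotype: Genotype = Genotype.WT
    age_group: AgeGroup = AgeGroup.adult
    cycle: Cycle = Cycle.light
    clock_start: float = 0.0  # seconds since midnight

    def __post_init__(self):
        if not (0.0 <= self.clock_start < 86400.0):
            raise ValueError("clock_start must lie in [0, 86400)")


def infer_channel_role(name: str) -> ChannelRole:
    """Infer a channel role from its name prefix (ctx/hpc/ref)."""
    low = name.strip().lower()
    if low.startswith("ctx"):
        if low.endswith(("_l", "l", "left")) and not low.endswith("al"):
            return ChannelRole.cortical_left
        if low.endswith(("_r", "r", "right")):
            return ChannelRole.cortical_right
        return ChannelRole.cortical_left
    if low.startswith("hpc") or low.startswith("hip"):
        return ChannelRole.hippocampal
    if low.startswith("ref"):
        return ChannelRole.reference
    return ChannelRole.other


@dataclass
class Recording:
    """Multichannel EEG recording.

    ``signals`` maps channel name -> float array in μV; every channel has
    the same length and sampling rate ``fs`` (Hz, default acquisition
    rate is 2000 Hz).
    """

    signals: dict[str, np.ndarray]
    fs: float
    channels: list[ChannelInfo] = field(default_factory=list)
    meta: SubjectMeta = field(default_factory=SubjectMeta)

    def __post_init__(self):
        if self.fs <= 0:
            raise FormatError(f"sampling rate must be positive, got {self.fs}")
        if not self.signals:
            raise InputError("recording has no channels")
        lengths = {len(v) for v in self.signals.values()}
        if len(lengths) != 1:
            raise FormatError(f"inconsistent channel lengths: {sorted(lengths)}")
        for name, sig in self.signals.items():
            arr = np.asarray(sig, dtype=float)
            if not np.all(np.isfinite(arr)):
                raise InputError(f"channel {name!r} contains non-finite samples")
            self.signals[name] = arr
        if not self.channels:
            self.channels = [ChannelInfo(n, infer_channel_role(n))
                             for n in self.signals]

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.signals.values())))

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def channel_names(self) -> list[str]:
        return list(self.signals.keys())

    def copy_with_signals(self, signals: dict[str, np.ndarray]) -> "Recording":
        return Recording(signals=dict(signals), fs=self.fs,
                         channels=list(self.channels), meta=self.meta)


@dataclass(frozen=True, order=True)
class Interval:
    """Half-open labeled interval ``[onset_s, onset_s + duration_s)``."""

    onset_s: float
    duration_s: float
    channel: str = "*"
    label: str = ""

    def __post_init__(self):
        if self.duration_s <= 0:
            raise FormatError(f"interval duration must be > 0, got {self.duration_s}")
        if self.onset_s < 0:
            raise FormatError(f"interval onset must be >= 0, got {self.onset_s}")

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass
class AnnotationTrack:
    """Sorted list of labeled intervals; overlap is permitted."""

    intervals: list[Interval] = field(default_factory=list)

    def __post_init__(self):
        self.intervals = sorted(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def for_channel(self, channel: str) -> "AnnotationTrack":
        """Intervals applying to ``channel`` (its own plus channel '*')."""
        return AnnotationTrack([iv for iv in self.intervals
                                if iv.channel in ("*", channel)])

    def with_label(self, label: str) -> "AnnotationTrack":
        return AnnotationTrack([iv for iv in self.intervals if iv.label == label])

    def union(self, other: "AnnotationTrack") -> "AnnotationTrack":
        return AnnotationTrack(self.intervals + list(other.intervals))

    def to_pairs(self) -> list[tuple[float, float]]:
        return [(iv.onset_s, iv.end_s) for iv in self.intervals]


# ---------------------------------------------------------------------------
# EDF writing (minimal plain-EDF encoder, 16-bit)
# ---------------------------------------------------------------------------

_EDF_DIG_MIN, _EDF_DIG_MAX = -32768, 32767


def _edf_field(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def _write_edf(rec: Recording, path: str) -> None:
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise FormatError("EDF writer requires an integer sampling rate; "
                          "use CSV for fractional rates")
    fs = int(round(fs))
    names = rec.channel_names
    n_sig = len(names)
    n_records = max(1, math.ceil(rec.n_samples / fs))

    # per-channel symmetric physical range covering the signal extrema
    phys_max = {n: max(1.0, math.ceil(float(np.max(np.abs(rec.signals[n])))))
                for n in names}
    gain = {n: 2.0 * phys_max[n] / (_EDF_DIG_MAX - _EDF_DIG_MIN) for n in names}

    buf = io.BytesIO()
    start = datetime.datetime(2000, 1, 1)
    buf.write(_edf_field("0", 8))
    buf.write(_edf_field(rec.meta.subject_id, 80))
    buf.write(_edf_field("qeeg", 80))
    buf.write(_edf_field(start.strftime("%d.%m.%y"), 8))
    buf.write(_edf_field(start.strftime("%H.%M.%S"), 8))
    buf.write(_edf_field(str(256 * (1 + n_sig)), 8))
    buf.write(_edf_field("", 44))
    buf.write(_edf_field(str(n_records), 8))
    buf.write(_edf_field("1", 8))                      # record duration, s
    buf.write(_edf_field(str(n_sig), 4))
    for name in names:
        buf.write(_edf_field(name, 16))
    for _ in names:
        buf.write(_edf_field("", 80))                  # transducer
    for _ in names:
        buf.write(_edf_field("uV", 8))
    for name in names:
        buf.write(_edf_field(f"{-phys_max[name]:g}", 8))
    for name in names:
        buf.write(_edf_field(f"{phys_max[name]:g}", 8))
    for _ in names:
        buf.write(_edf_field(str(_EDF_DIG_MIN), 8))
    for _ in names:
        buf.write(_edf_field(str(_EDF_DIG_MAX), 8))
    for _ in names:
        buf.write(_edf_field("", 80))                  # prefiltering
    for _ in names:
        buf.write(_edf_field(str(fs), 8))
    for _ in names:
        buf.write(_edf_field("", 32))

    # digitize; recordings not a whole number of seconds are zero-padded
    digital = {}
    for name in names:
        sig = rec.signals[name]
        padded = np.zeros(n_records * fs)
        padded[: len(sig)] = sig
        dig = np.round((padded + phys_max[name]) / gain[name] + _EDF_DIG_MIN)
        digital[name] = np.clip(dig, _EDF_DIG_MIN, _EDF_DIG_MAX).astype("<i2")

    for r in range(n_records):
        for name in names:
            buf.write(digital[name][r * fs:(r + 1) * fs].tobytes())

    with open(path, "wb") as fh:
        fh.write(buf.getvalue())


def _read_edf(path: str) -> Recording:
    import mne

    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # pragma: no cover - delegated parser
        raise FormatError(f"cannot parse EDF file {path}: {exc}") from exc
    fs = float(raw.info["sfreq"])
    if fs <= 0:
        raise FormatError(f"non-positive sampling rate in {path}")
    data = raw.get_data() * 1e6  # MNE returns volts
    signals = {name: data[i] for i, name in enumerate(raw.ch_names)}
    meta = SubjectMeta(subject_id=(raw.info.get("subject_info") or {}).get("his_id", "unknown") or "unknown")
    return Recording(signals=signals, fs=fs, meta=meta)


# ---------------------------------------------------------------------------
# CSV
# ---------------------------------------------------------------------------

def _read_csv(path: str, fs: float | None) -> Recording:
    try:
        with open(path) as fh:
            header = fh.readline()
        sep = "\t" if header.count("\t") >= header.count(",") and "\t" in header \
            else ","
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    except Exception as exc:
        raise FormatError(f"cannot parse CSV file {path}: {exc}") from exc
    if df.shape[1] < 2:
        raise FormatError("CSV recording needs a time/index column plus >=1 channel")
    tcol = df.columns[0]
    t = df[tcol].to_numpy(dtype=float)
    if fs is None:
        if len(t) < 2:
            raise FormatError("cannot infer fs from a CSV with < 2 rows; pass fs=")
        dt = float(np.median(np.diff(t)))
        if dt <= 0:
            raise FormatError("non-increasing time column; cannot infer fs")
        # integer first column means sample index, not seconds
        fs = 1.0 / dt if not np.allclose(np.diff(t), 1.0) else 2000.0
    if fs <= 0:
        raise FormatError(f"sampling rate must be positive, got {fs}")
    signals = {str(c): df[c].to_numpy(dtype=float) for c in df.columns[1:]}
    return Recording(signals=signals, fs=float(fs))


def _write_csv(rec: Recording, path: str) -> None:
    n = rec.n_samples
    out = pd.DataFrame({"t": np.arange(n) / rec.fs})
    for name in rec.channel_names:
        out[name] = rec.signals[name]
    # default float formatting = shortest round-trip repr -> exact reload
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def read_recording(path: str, format: str = "auto", fs: float | None = None,
                   meta: SubjectMeta | None = None) -> Recording:
    """Read an EEG recording from EDF or CSV.

    ``format='auto'`` dispatches on the file extension. For CSV the first
    column is time (s) or sample index and the remaining columns are
    channels; ``fs`` overrides the rate inferred from the time column.
    Channel roles are inferred from name prefixes (``ctx``/``hpc``/``ref``).
    """
    if not os.path.exists(path):
        raise InputError(f"recording file not found: {path}")
    if format == "auto":
        format = "edf" if str(path).lower().endswith(".edf") else "csv"
    if format == "edf":
        rec = _read_edf(path)
    elif format == "csv":
        rec = _read_csv(path, fs)
    else:
        raise InputError(f"unknown recording format {format!r}")
    if meta is not None:
        rec.meta = meta
    return rec


def write_recording(rec: Recording, path: str, format: str = "auto") -> None:
    """Write a recording as EDF (16-bit, round-trip error ≤ range/2^16) or CSV (exact)."""
    if format == "auto":
        format = "edf" if str(path).lower().endswith(".edf") else "csv"
    if format == "edf":
        _write_edf(rec, path)
    elif format == "csv":
        _write_csv(rec, path)
    else:
        raise InputError(f"unknown recording format {format!r}")


_ANNOT_COLUMNS = ["onset_s", "duration_s", "channel", "label"]


def read_annotations(path: str) -> AnnotationTrack:
    """Read an interval TSV (onset_s, duration_s, channel, label)."""
    if not os.path.exists(path):
        raise InputError(f"annotation file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype={"channel": str, "label": str})
    missing = [c for c in _ANNOT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"annotation file {path} is missing columns: {missing}")
    intervals = [Interval(onset_s=float(r.onset_s), duration_s=float(r.duration_s),
                          channel=str(r.channel), label=str(r.label))
                 for r in df.itertuples()]
    return AnnotationTrack(intervals)


def write_annotations(track: AnnotationTrack, path: str) -> None:
    """Write an AnnotationTrack as TSV; lossless round-trip (17 significant digits)."""
    df = pd.DataFrame(
        [(iv.onset_s, iv.duration_s, iv.channel, iv.label) for iv in track],
        columns=_ANNOT_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
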