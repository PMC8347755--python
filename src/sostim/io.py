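"""Record/event file I/O and sample-by-sample re-streaming.

Signals are stored either as EDF (16-bit, physical dimension uV) or as
delimited text (CSV with a ``time`` column in seconds and one column per
channel, amplitudes in uV).  Event logs and ground-truth sidecars are CSV.
:func:`restream` replays a stored record in causal chunks to emulate
real-time acquisition; consumers must behave identically for any chunk
size.

EDF reading goes through :func:`mne.io.read_raw_edf`.  Writing uses a
minimal built-in EDF encoder (one 1-s data record per second, int16
samples) because the pre-installed stack has no EDF export path.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Iterator, Optional

import numpy as np
import pandas as pd

from sostim.synth import EEGRecord

__all__ = [
    "Event",
    "EventLog",
    "SampleStream",
    "restream",
    "read_record",
    "write_record",
    "write_truth_sidecar",
    "read_truth_sidecar",
    "resample_record",
]

EVENT_KINDS = ("detection", "stim1", "stim2", "pll_stim")


class FormatError(ValueError):
    """Raised for unreadable or incomplete signal files."""


# ---------------------------------------------------------------------------
# Event log


@dataclass(frozen=True)
class Event:
    time_s: float
    kind: str
    method: str = ""
    value: float = float("nan")

    def __post_init__(self):
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"kind must be one of {EVENT_KINDS}, got {self.kind!r}")


@dataclass
class EventLog:
    """Ordered detection/stimulation marker list (times non-decreasing)."""

    events: list[Event] = field(default_factory=list)

    def append(self, event: Event) -> None:
        if self.events and event.time_s < self.events[-1].time_s - 1e-12:
            raise ValueError("event times must be non-decreasing")
        self.events.append(event)

    def times(self, kind: Optional[str] = None) -> np.ndarray:
        return np.asarray(
            [e.time_s for e in self.events if kind is None or e.kind == kind], dtype=float)

    def of_kind(self, kind: str) -> list[Event]:
        return [e for e in self.events if e.kind == kind]

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self) -> Iterator[Event]:
        return iter(self.events)

    def __eq__(self, other) -> bool:
        if not isinstance(other, EventLog):
            return NotImplemented
        if len(self) != len(other):
            return False
        for a, b in zip(self.events, other.events):
            if (a.time_s, a.kind, a.method) != (b.time_s, b.kind, b.method):
                return False
            if not (a.value == b.value or (np.isnan(a.value) and np.isnan(b.value))):
                return False
        return True

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": [e.time_s for e in self.events],
                "kind": [e.kind for e in self.events],
                "method": [e.method for e in self.events],
                "value": [e.value for e in self.events],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "EventLog":
        df = pd.read_csv(path)
        log = cls()
        for row in df.itertuples(index=False):
            method = "" if pd.isna(row.method) else str(row.method)
            log.append(Event(float(row.time_s), str(row.kind), method, float(row.value)))
        return log


# ---------------------------------------------------------------------------
# Streaming


class SampleStream:
    """Strictly sequential replay of an :class:`EEGRecord`.

    Each :meth:`pull` yields the next ``chunk`` samples (channels x k);
    there is no lookahead, and the concatenation of all pulled chunks
    equals the source signal exactly.
    """

    def __init__(self, record: EEGRecord, chunk: int = 1):
        if chunk < 1:
            raise ValueError("chunk must be >= 1")
        self.record = record
        self.chunk = int(chunk)
        self.cursor = 0

    @property
    def fs(self) -> float:
        return self.record.fs

    @property
    def channel_labels(self) -> list[str]:
        return self.record.channel_labels

    @property
    def exhausted(self) -> bool:
        return self.cursor >= self.record.n_samples

    def pull(self) -> Optional[np.ndarray]:
        """Next chunk of samples, or None once the stream is exhausted."""
        if self.exhausted:
            return None
        stop = min(self.cursor + self.chunk, self.record.n_samples)
        out = self.record.data[:, self.cursor:stop]
        self.cursor = stop
        return out

    def __iter__(self) -> Iterator[np.ndarray]:
        while True:
            chunk = self.pull()
            if chunk is None:
                return
            yield chunk


def restream(record: EEGRecord, chunk: int = 1) -> SampleStream:
    """Replay ``record`` in causal chunks (chunk larger than the record
    simply yields one chunk)."""
    return SampleStream(record, chunk=chunk)


# ---------------------------------------------------------------------------
# CSV signals


def _write_csv(record: EEGRecord, path) -> None:
    df = pd.DataFrame({"time": record.times})
    for i, lab in enumerate(record.channel_labels):
        df[lab] = record.data[i]
    df.to_csv(path, index=False)


def _read_csv(path) -> EEGRecord:
    df = pd.read_csv(path)
    if "time" not in df.columns:
        raise FormatError(f"CSV {path} lacks a 'time' column; columns: {list(df.columns)}")
    t = df["time"].to_numpy(dtype=float)
    if t.size < 2:
        raise FormatError("CSV must contain at least two samples to infer fs")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise FormatError("CSV time column is not uniformly sampled")
    fs = 1.0 / dt[0]
    labels = [c for c in df.columns if c != "time"]
    data = df[labels].to_numpy(dtype=float).T
    return EEGRecord(data=data, fs=round(fs, 6), channel_labels=labels)


# ---------------------------------------------------------------------------
# EDF


def _edf_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def _write_edf(record: EEGRecord, path) -> None:
    """Minimal EDF writer: 1-s data records, int16, physical dimension uV.

    A trailing partial second is padded by repeating the last sample; the
    reader therefore returns whole seconds.
    """
    fs = record.fs
    if abs(fs - round(fs)) > 1e-9:
        raise FormatError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))  # samples per data record (1 s records)
    n_ch = record.data.shape[0]
    n_rec = int(np.ceil(record.n_samples / spr))
    data = record.data
    pad = n_rec * spr - record.n_samples
    if pad:
        data = np.hstack([data, np.repeat(data[:, -1:], pad, axis=1)])

    pmax = float(np.max(np.abs(data)))
    pmax = max(pmax, 1.0)
    dmin, dmax = -32768, 32767
    scale = (2 * pmax) / (dmax - dmin)
    digital = np.clip(np.round((data + pmax) / scale) + dmin, dmin, dmax).astype("<i2")

    header_bytes = 256 * (1 + n_ch)
    with open(path, "wb") as fh:
        fh.write(_edf_field("0", 8))
        fh.write(_edf_field("X X X X", 80))               # patient id
        fh.write(_edf_field("Startdate X X X X", 80))     # recording id
        fh.write(_edf_field("01.01.00", 8))
        fh.write(_edf_field("00.00.00", 8))
        fh.write(_edf_field(header_bytes, 8))
        fh.write(_edf_field("", 44))
        fh.write(_edf_field(n_rec, 8))
        fh.write(_edf_field("1", 8))                      # 1 s per record
        fh.write(_edf_field(n_ch, 4))
        for lab in record.channel_labels:
            fh.write(_edf_field(lab, 16))
        for _ in range(n_ch):
            fh.write(_edf_field("", 80))                  # transducer
        for _ in range(n_ch):
            fh.write(_edf_field("uV", 8))
        for _ in range(n_ch):
            fh.write(_edf_field(f"{-pmax:.6g}"[:8], 8))
        for _ in range(n_ch):
            fh.write(_edf_field(f"{pmax:.6g}"[:8], 8))
        for _ in range(n_ch):
            fh.write(_edf_field(dmin, 8))
        for _ in range(n_ch):
            fh.write(_edf_field(dmax, 8))
        for _ in range(n_ch):
            fh.write(_edf_field("", 80))                  # prefiltering
        for _ in range(n_ch):
            fh.write(_edf_field(spr, 8))
        for _ in range(n_ch):
            fh.write(_edf_field("", 32))
        for r in range(n_rec):
            sl = slice(r * spr, (r + 1) * spr)
            for ch in range(n_ch):
                fh.write(digital[ch, sl].tobytes())


def _read_edf(path) -> EEGRecord:
    import mne

    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # pragma: no cover - corrupt-file path
        raise FormatError(f"unreadable EDF header in {path}: {exc}") from exc
    data = raw.get_data(units="uV")
    return EEGRecord(data=np.asarray(data, dtype=float), fs=float(raw.info["sfreq"]),
                     channel_labels=list(raw.ch_names))


# ---------------------------------------------------------------------------
# dispatch


def _infer_format(path, fmt: Optional[str]) -> str:
    if fmt is not None:
        return fmt
    suffix = Path(path).suffix.lower()
    if suffix == ".edf":
        return "edf"
    if suffix in (".csv", ".txt"):
        return "csv"
    raise FormatError(f"cannot infer format from {path}; pass format='edf' or 'csv'")


def read_record(path, format: Optional[str] = None,
                required_channels: Optional[Iterable[str]] = None) -> EEGRecord:
    """Read a signal file (EDF or CSV) into an :class:`EEGRecord` in uV."""
    fmt = _infer_format(path, format)
    if not Path(path).exists():
        raise FileNotFoundError(path)
    record = _read_edf(path) if fmt == "edf" else _read_csv(path)
    if required_channels is not None:
        missing = [c for c in required_channels if c not in record.channel_labels]
        if missing:
            raise FormatError(
                f"missing channels {missing}; available: {record.channel_labels}")
    return record


def write_record(record: EEGRecord, path, format: Optional[str] = None) -> None:
    """Write a record as EDF or CSV (format inferred from the suffix)."""
    fmt = _infer_format(path, format)
    if fmt == "edf":
        _write_edf(record, path)
    else:
        _write_csv(record, path)


def write_truth_sidecar(record: EEGRecord, path) -> None:
    """Ground-truth sidecar CSV (columns time_s,label): SO troughs and the
    per-30 s sleep-stage codes at their epoch start times."""
    rows = []
    if record.truth_troughs is not None:
        rows += [(float(t), "trough") for t in record.truth_troughs]
    if record.stage_labels is not None:
        rows += [(30.0 * i, stage) for i, stage in enumerate(record.stage_labels)]
    df = pd.DataFrame(rows, columns=["time_s", "label"]).sort_values("time_s", kind="stable")
    df.to_csv(path, index=False)


def read_truth_sidecar(path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# resampling


def resample_record(record: EEGRecord, target_fs: float) -> EEGRecord:
    """Anti-aliased decimation to ``target_fs`` (upsampling unsupported).

    Ground-truth trough times and stage labels are carried over unchanged
    (they live on the seconds axis).
    """
    if target_fs > record.fs:
        raise ValueError(f"upsampling not supported ({record.fs} -> {target_fs} Hz)")
    if target_fs == record.fs:
        return EEGRecord(record.data.copy(), record.fs, list(record.channel_labels),
                         record.stage_labels, record.truth_troughs)
    from scipy.signal import resample_poly

    ratio = Fraction(target_fs / record.fs).limit_denominator(10000)
    data = resample_poly(record.data, ratio.numerator, ratio.denominator, axis=1)
    return EEGRecord(data=data, fs=float(target_fs), channel_labels=list(record.channel_labels),
                     stage_labels=record.stage_labels, truth_troughs=record.truth_troughs)
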