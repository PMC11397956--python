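"""Readers and writers for the three device-stream dialects.

Three kinds of stream are handled, all normalised onto Unix epoch
milliseconds on load:

* **criterion ECG** — plain text, a header line carrying the recording-start
  epoch followed by one voltage sample (µV) per row, sampled at 1000 Hz by
  a laboratory three-lead system;
* **chest-sensor ECG** — CSV of 16-sample voltage packets (µV) at 500 Hz,
  each packet stamped with a relative timestamp (ms since device
  activation), plus a global start epoch;
* **RR-interval device export** — CSV of per-beat RR′ values with
  timestamps counted in seconds from the FIT epoch (midnight
  31 December 1989 UTC), as produced by converting a sports watch's
  activity file.

No resampling or filtering is ever applied on load; records keep their
native sampling rate and raw voltages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ECGRecord",
    "RRSeries",
    "StreamBundle",
    "FormatError",
    "FIT_OFFSET_S",
    "SENTINEL_RR_MS",
    "fit_epoch_to_unix_ms",
    "unix_ms_to_fit_epoch_s",
    "read_criterion_ecg",
    "write_criterion_ecg",
    "read_packet_ecg",
    "write_packet_ecg",
    "read_rr_stream",
    "write_rr_stream",
    "truncate_at_disconnection",
]

#: Calendar seconds from 1970-01-01T00:00:00Z to 1989-12-31T00:00:00Z:
#: 20 years × 365 d + 5 leap days − 1 d = 7304 d.
FIT_OFFSET_S = 631_065_600

#: RR′ code emitted by the watch when no beat was detected in the
#: preceding 5 s window.
SENTINEL_RR_MS = 5000.0

PACKET_SIZE = 16


class FormatError(ValueError):
    """A stream file violates its dialect."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class ECGRecord:
    """Uniformly sampled ECG voltages with a global start time.

    Sample ``i`` is at ``start_epoch_ms + i * 1000 / fs`` ms. ``dropouts``
    lists half-open ``[start_ms, stop_ms)`` epochs where the transport lost
    packets; the affected samples are zero-filled so the record stays
    uniform.
    """

    samples: np.ndarray
    fs: float
    start_epoch_ms: float
    source_label: str = "criterion"
    dropouts: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("record needs a non-empty 1-D sample array")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def period_ms(self) -> float:
        return 1000.0 / self.fs

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def end_epoch_ms(self) -> float:
        """Epoch just past the last sample (half-open span end)."""
        return self.start_epoch_ms + self.n_samples * self.period_ms

    def times_ms(self) -> np.ndarray:
        return self.start_epoch_ms + np.arange(self.n_samples) * self.period_ms

    def sample_time_ms(self, index: int | np.ndarray) -> float | np.ndarray:
        return self.start_epoch_ms + np.asarray(index) * self.period_ms

    def index_at(self, epoch_ms: float) -> int:
        """Nearest sample index for an epoch (clipped to the record)."""
        i = int(round((epoch_ms - self.start_epoch_ms) / self.period_ms))
        return min(max(i, 0), self.n_samples - 1)

    def slice_time(self, t0_ms: float, t1_ms: float) -> "ECGRecord":
        """Sub-record covering ``[t0_ms, t1_ms)``; endpoints snap to samples."""
        i0 = max(0, int(np.ceil((t0_ms - self.start_epoch_ms) / self.period_ms)))
        i1 = min(self.n_samples, int(np.ceil((t1_ms - self.start_epoch_ms) / self.period_ms)))
        if i1 <= i0:
            raise ValueError("empty slice")
        return ECGRecord(
            samples=self.samples[i0:i1].copy(),
            fs=self.fs,
            start_epoch_ms=self.start_epoch_ms + i0 * self.period_ms,
            source_label=self.source_label,
            dropouts=[d for d in self.dropouts if d[1] > t0_ms and d[0] < t1_ms],
        )

    def shifted(self, offset_ms: float) -> "ECGRecord":
        return ECGRecord(
            samples=self.samples,
            fs=self.fs,
            start_epoch_ms=self.start_epoch_ms + offset_ms,
            source_label=self.source_label,
            dropouts=[(a + offset_ms, b + offset_ms) for a, b in self.dropouts],
        )


@dataclass
class RRSeries:
    """Per-beat RR′ rows: a beat time and the interval ending at that beat.

    ``beat_epoch_ms[i]`` is the epoch of the i-th detected beat carrying an
    RR′ value; ``rr_ms[i]`` is the interval that ends there. Device exports
    may interleave sentinel rows (RR′ = 5000 ms, "no beat in the last 5 s");
    those are excluded from the arrays but counted in ``n_sentinels`` and
    marked per original row in ``sentinel_flags``. For a sentinel-free
    series built from beat times, ``beat_epoch_ms`` equals the cumulative
    sum of ``rr_ms`` from the first beat.
    """

    beat_epoch_ms: np.ndarray
    rr_ms: np.ndarray
    sentinel_flags: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))
    source_label: str = "rr_device"

    def __post_init__(self) -> None:
        self.beat_epoch_ms = np.asarray(self.beat_epoch_ms, dtype=float)
        self.rr_ms = np.asarray(self.rr_ms, dtype=float)
        self.sentinel_flags = np.asarray(self.sentinel_flags, dtype=bool)
        if self.beat_epoch_ms.size != self.rr_ms.size:
            raise ValueError("beat_epoch_ms and rr_ms must align row-wise")
        if self.beat_epoch_ms.size and np.any(np.diff(self.beat_epoch_ms) <= 0):
            raise ValueError("beat times must be strictly increasing")
        if np.any(self.rr_ms <= 0):
            raise ValueError("RR intervals must be positive after sentinel removal")

    @classmethod
    def from_beat_times(cls, beat_epoch_ms: Sequence[float], source_label: str = "derived") -> "RRSeries":
        t = np.asarray(beat_epoch_ms, dtype=float)
        if t.size < 2:
            raise ValueError("need at least two beats to form intervals")
        return cls(
            beat_epoch_ms=t[1:],
            rr_ms=np.diff(t),
            sentinel_flags=np.zeros(t.size - 1, dtype=bool),
            source_label=source_label,
        )

    @property
    def n_beats(self) -> int:
        return int(self.beat_epoch_ms.size)

    @property
    def n_sentinels(self) -> int:
        return int(self.sentinel_flags.sum())

    def beat_times_full(self) -> np.ndarray:
        """Beat times including the implied beat opening the first interval."""
        if self.n_beats == 0:
            return np.zeros(0)
        return np.concatenate([[self.beat_epoch_ms[0] - self.rr_ms[0]], self.beat_epoch_ms])

    def shifted(self, offset_ms: float) -> "RRSeries":
        return RRSeries(
            beat_epoch_ms=self.beat_epoch_ms + offset_ms,
            rr_ms=self.rr_ms,
            sentinel_flags=self.sentinel_flags,
            source_label=self.source_label,
        )


@dataclass
class StreamBundle:
    """Criterion record plus at least one device stream, on one timeline."""

    criterion: ECGRecord
    device_ecg: ECGRecord | None = None
    device_rr: RRSeries | None = None
    activity_label: str = "rest_pre"
    subject: str = "S00"
    mode: str = "running"

    def __post_init__(self) -> None:
        if self.device_ecg is None and self.device_rr is None:
            raise ValueError("bundle needs at least one device stream")


# ---------------------------------------------------------------------------
# FIT epoch
# ---------------------------------------------------------------------------


def fit_epoch_to_unix_ms(fit_ts_s):
    """Convert seconds since the FIT epoch (1989-12-31T00:00Z) to Unix ms."""
    ts = np.asarray(fit_ts_s, dtype=float)
    if np.any(ts < 0):
        raise ValueError("FIT timestamps are unsigned; got a negative value")
    out = (ts + FIT_OFFSET_S) * 1000.0
    return float(out) if np.isscalar(fit_ts_s) else out


def unix_ms_to_fit_epoch_s(unix_ms):
    """Inverse of :func:`fit_epoch_to_unix_ms`."""
    ms = np.asarray(unix_ms, dtype=float)
    out = ms / 1000.0 - FIT_OFFSET_S
    if np.any(out < 0):
        raise ValueError("epoch precedes the FIT epoch")
    return float(out) if np.isscalar(unix_ms) else out


# ---------------------------------------------------------------------------
# criterion dialect
# ---------------------------------------------------------------------------

_HEADER_KEY = "start_epoch_ms"


def _parse_header(line: str) -> dict[str, float]:
    fields = {}
    for token in line.lstrip("#").replace(",", " ").split():
        if "=" in token:
            key, _, val = token.partition("=")
            try:
                fields[key.strip()] = float(val)
            except ValueError as exc:
                raise FormatError(f"unparseable header token {token!r}") from exc
    return fields


def read_criterion_ecg(path: str | Path, fs: float = 1000.0) -> ECGRecord:
    """Read a criterion ECG text export: header line, then one µV per row."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        fields = _parse_header(header)
        if _HEADER_KEY not in fields:
            raise FormatError(f"{path}: header must carry {_HEADER_KEY}=<epoch>")
        body = fh.read().split()
    if not body:
        raise FormatError(f"{path}: no samples")
    try:
        samples = np.array(body, dtype=float)
    except ValueError:
        for row, token in enumerate(body, start=2):
            try:
                float(token)
            except ValueError:
                raise FormatError(f"{path}: non-numeric value {token!r} at row {row}") from None
        raise
    return ECGRecord(
        samples=samples,
        fs=fields.get("fs", fs),
        start_epoch_ms=fields[_HEADER_KEY],
        source_label="criterion",
    )


def write_criterion_ecg(record: ECGRecord, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"{_HEADER_KEY}={record.start_epoch_ms:.0f} fs={record.fs:g}\n")
        np.savetxt(fh, record.samples, fmt="%.6g")
    return path


# ---------------------------------------------------------------------------
# packet dialect (chest sensor)
# ---------------------------------------------------------------------------


def read_packet_ecg(path: str | Path, dropout_factor: float = 1.5) -> ECGRecord:
    """Reconstruct a chest-sensor record from its 16-sample packet CSV.

    The packet timestamp marks the packet's first sample; samples are spaced
    at the nominal period. Gaps between consecutive packet timestamps larger
    than ``dropout_factor`` packet durations are recorded as dropout
    segments and zero-filled to keep the record uniform.
    """
    path = Path(path)
    with open(path) as fh:
        header = _parse_header(fh.readline())
        if _HEADER_KEY not in header:
            raise FormatError(f"{path}: header must carry {_HEADER_KEY}=<epoch>")
        df = pd.read_csv(fh)
    value_cols = [c for c in df.columns if c.startswith("v")]
    if len(value_cols) != PACKET_SIZE:
        raise FormatError(
            f"{path}: expected {PACKET_SIZE} value columns v0..v15, found {len(value_cols)}"
        )
    if df.empty:
        raise FormatError(f"{path}: no packets")
    if df[value_cols].isna().any().any():
        raise FormatError(f"{path}: packet with missing values")
    rel = df["relative_timestamp_ms"].to_numpy(dtype=float)
    if np.any(np.diff(rel) <= 0):
        raise FormatError(f"{path}: packet timestamps must be strictly increasing")

    fs = header.get("fs")
    packet_gaps = np.diff(rel)
    if fs is None:
        if packet_gaps.size == 0:
            raise FormatError(f"{path}: cannot infer fs from a single packet without header fs")
        fs = PACKET_SIZE * 1000.0 / float(np.median(packet_gaps))
    period = 1000.0 / fs
    packet_dur = PACKET_SIZE * period

    values = df[value_cols].to_numpy(dtype=float)
    n_total = int(round((rel[-1] - rel[0]) / period)) + PACKET_SIZE
    samples = np.zeros(n_total)
    for i, r in enumerate(rel):
        j = int(round((r - rel[0]) / period))
        samples[j : j + PACKET_SIZE] = values[i]

    start_epoch = header[_HEADER_KEY] + rel[0]
    dropouts = []
    for i in np.nonzero(packet_gaps > dropout_factor * packet_dur)[0]:
        gap_start = header[_HEADER_KEY] + rel[i] + packet_dur
        gap_stop = header[_HEADER_KEY] + rel[i + 1]
        dropouts.append((gap_start, gap_stop))
    return ECGRecord(
        samples=samples,
        fs=fs,
        start_epoch_ms=start_epoch,
        source_label="chest_sensor",
        dropouts=dropouts,
    )


def write_packet_ecg(
    record: ECGRecord,
    path: str | Path,
    keep_packet: np.ndarray | None = None,
) -> Path:
    """Write a record as 16-sample packets; ``keep_packet`` masks dropouts.

    A trailing partial packet is dropped. ``keep_packet`` is a boolean mask
    over packet index; omitted packets simply do not appear in the file,
    emulating transport loss.
    """
    path = Path(path)
    n_packets = record.n_samples // PACKET_SIZE
    if n_packets == 0:
        raise ValueError("record shorter than one packet")
    if keep_packet is None:
        keep_packet = np.ones(n_packets, dtype=bool)
    keep_packet = np.asarray(keep_packet, dtype=bool)
    if keep_packet.size != n_packets:
        raise ValueError("keep_packet mask must have one entry per packet")
    packet_dur = PACKET_SIZE * record.period_ms
    rows = []
    for i in np.nonzero(keep_packet)[0]:
        vals = record.samples[i * PACKET_SIZE : (i + 1) * PACKET_SIZE]
        rows.append([i * packet_dur, *vals])
    df = pd.DataFrame(rows, columns=["relative_timestamp_ms"] + [f"v{k}" for k in range(PACKET_SIZE)])
    with open(path, "w") as fh:
        fh.write(f"# {_HEADER_KEY}={record.start_epoch_ms:.0f} fs={record.fs:g}\n")
        df.to_csv(fh, index=False, float_format="%.6g")
    return path


# ---------------------------------------------------------------------------
# RR-device dialect
# ---------------------------------------------------------------------------


def read_rr_stream(path: str | Path, sentinel_rr_ms: float = SENTINEL_RR_MS) -> RRSeries:
    """Read an RR-device CSV (FIT-epoch timestamps, per-beat RR′ in ms).

    Rows whose RR′ equals the sentinel code are non-detections: they are
    flagged and excluded from the beat/interval arrays.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    for col in ("fit_timestamp_s", "rr_ms"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    ts = df["fit_timestamp_s"].to_numpy(dtype=float)
    if np.any(np.diff(ts) <= 0):
        raise FormatError(f"{path}: timestamps must be strictly increasing")
    rr = df["rr_ms"].to_numpy(dtype=float)
    flags = rr == sentinel_rr_ms
    beat_ms = fit_epoch_to_unix_ms(ts[~flags])
    return RRSeries(
        beat_epoch_ms=beat_ms,
        rr_ms=rr[~flags],
        sentinel_flags=flags,
        source_label="rr_device",
    )


def write_rr_stream(
    series: RRSeries,
    path: str | Path,
    sentinel_epochs_ms: Sequence[float] = (),
    sentinel_rr_ms: float = SENTINEL_RR_MS,
) -> Path:
    """Write an RR series in the device dialect; sentinel rows interleaved."""
    path = Path(path)
    times = list(series.beat_epoch_ms)
    rrs = list(series.rr_ms)
    for t in sentinel_epochs_ms:
        times.append(t)
        rrs.append(sentinel_rr_ms)
    order = np.argsort(times, kind="stable")
    times = np.asarray(times)[order]
    rrs = np.asarray(rrs)[order]
    df = pd.DataFrame(
        {
            "fit_timestamp_s": unix_ms_to_fit_epoch_s(times),
            "rr_ms": rrs,
            "hr_bpm": np.where(rrs == sentinel_rr_ms, 0.0, np.round(60000.0 / rrs, 1)),
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")
    return path


# ---------------------------------------------------------------------------
# disconnection truncation
# ---------------------------------------------------------------------------


def truncate_at_disconnection(
    record: ECGRecord,
    window_s: float = 2.0,
    flat_range_uv: float = 50.0,
) -> tuple[ECGRecord | None, dict]:
    """Cut a record at the first flat (disconnected) window.

    A poor electrode connection shows as almost absent voltage: the first
    sliding window whose peak-to-peak range falls below ``flat_range_uv``
    marks the cut; only data before it are kept. Returns ``(prefix, report)``
    where ``prefix`` is ``None`` when the record is flat from the start.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    win = max(2, int(round(window_s * record.fs)))
    hop = max(1, win // 2)
    x = record.samples
    cut_index: int | None = None
    for start in range(0, max(1, x.size - win + 1), hop):
        seg = x[start : start + win]
        if seg.size >= 2 and float(np.ptp(seg)) < flat_range_uv:
            cut_index = start
            break
    if cut_index is None:
        return record, {"cut": False, "reason": "no flat segment detected"}
    cut_epoch = record.sample_time_ms(cut_index)
    report = {
        "cut": True,
        "cut_index": int(cut_index),
        "cut_epoch_ms": float(cut_epoch),
        "reason": f"peak-to-peak range below {flat_range_uv:g} µV over {window_s:g} s",
    }
    if cut_index == 0:
        report["total_disconnection"] = True
        return None, report
    prefix = ECGRecord(
        samples=x[:cut_index].copy(),
        fs=record.fs,
        start_epoch_ms=record.start_epoch_ms,
        source_label=record.source_label,
        dropouts=[d for d in record.dropouts if d[0] < cut_epoch],
    )
    return prefix, report
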