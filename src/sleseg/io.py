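"""Core data model for LFP recordings, per-sample labels and event intervals.

A :class:`Recording` is one single-channel local field potential trace with its
sampling rate and experimental metadata (group, hemisphere, treatment, animal,
slice).  Seizure-like events (SLEs) are represented either as a per-sample
binary :class:`LabelSeries` or as an interval :class:`EventList`; the two views
are interconvertible (see :mod:`sleseg.postprocess`).

Interval convention: half-open, 0-based sample indices ``[onset, offset)`` so
that durations and concatenations are exact integer arithmetic.

Supported on-disk formats: a greppable headered CSV, single-channel EDF
(16-bit, hence quantized to the physical range / 2**15), and a compact binary
container (``.npy`` samples with a JSON sidecar).  Event lists round-trip
through plain ``onset_s<TAB>offset_s`` text files, which double as the manual
review/correction format.
"""

from __future__ import annotations

import json
import logging
import struct
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from scipy import signal as sps

logger = logging.getLogger(__name__)

__all__ = [
    "Recording",
    "LabelSeries",
    "Event",
    "EventList",
    "SegmentBatch",
    "FormatError",
    "read_recording",
    "write_recording",
    "read_events",
    "write_events",
    "select_analysis_window",
    "downsample",
    "segment",
    "standardize_segment",
]


class FormatError(ValueError):
    """Malformed or unsupported recording file."""


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------

_META_KEYS = ("group", "hemisphere", "treatment", "animal_id", "slice_id")


@dataclass
class Recording:
    """One single-channel LFP trace.

    Parameters
    ----------
    samples : ndarray
        Field-potential values in arbitrary units.
    sampling_rate_hz : float
        Acquisition rate (the experimental chain samples at 2,000 Hz; the
        classifier operates on a 125-Hz downsampled copy).
    recording_id : str
        Unique identifier.
    meta : dict
        Experimental metadata; recognised keys are ``group``
        (naive/sham/glioma), ``hemisphere`` (ipsi/contra/none), ``treatment``
        (ctrl/CNB60/CNB120), ``animal_id`` and ``slice_id``.
    """

    samples: np.ndarray
    sampling_rate_hz: float
    recording_id: str = "rec"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be > 0")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    def copy_with(self, **kw) -> "Recording":
        return replace(self, **kw)


@dataclass
class LabelSeries:
    """Per-sample binary SLE mask aligned to a (usually 125-Hz) recording."""

    labels: np.ndarray
    sampling_rate_hz: float = 125.0

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if not np.isin(lab, (0, 1)).all():
            raise ValueError("labels must be binary")
        self.labels = lab.astype(np.uint8)
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be > 0")

    def __len__(self) -> int:
        return self.labels.size


@dataclass(frozen=True)
class Event:
    """Half-open sample interval ``[onset, offset)``."""

    onset: int
    offset: int

    def __post_init__(self) -> None:
        if not (0 <= self.onset < self.offset):
            raise ValueError(f"invalid event [{self.onset}, {self.offset})")

    def duration_s(self, rate_hz: float) -> float:
        return (self.offset - self.onset) / rate_hz


@dataclass
class EventList:
    """Sorted, non-overlapping events over an analyzed window.

    ``total_window_s`` is the analyzed duration the events live in; event
    rates and fractions are computed against it.
    """

    events: list[Event]
    sampling_rate_hz: float
    total_window_s: float

    def __post_init__(self) -> None:
        self.events = [e if isinstance(e, Event) else Event(*e) for e in self.events]
        if self.sampling_rate_hz <= 0 or self.total_window_s <= 0:
            raise ValueError("rate and window must be > 0")
        n_total = int(round(self.total_window_s * self.sampling_rate_hz))
        prev_off = 0
        for e in self.events:
            if e.onset < prev_off:
                raise ValueError("events must be sorted and non-overlapping")
            if e.offset > n_total:
                raise ValueError("event beyond analyzed window")
            prev_off = e.offset

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self) -> Iterator[Event]:
        return iter(self.events)

    @property
    def durations_s(self) -> np.ndarray:
        return np.array([e.duration_s(self.sampling_rate_hz) for e in self.events])

    def onsets_s(self) -> np.ndarray:
        return np.array([e.onset / self.sampling_rate_hz for e in self.events])

    def offsets_s(self) -> np.ndarray:
        return np.array([e.offset / self.sampling_rate_hz for e in self.events])

    def at_rate(self, rate_hz: float) -> "EventList":
        """Re-express event boundaries at another sampling rate."""
        if rate_hz == self.sampling_rate_hz:
            return self
        q = rate_hz / self.sampling_rate_hz
        evs = []
        for e in self.events:
            onset = int(round(e.onset * q))
            offset = max(onset + 1, int(round(e.offset * q)))
            evs.append(Event(onset, offset))
        return EventList(evs, rate_hz, self.total_window_s)


@dataclass
class SegmentBatch:
    """Fixed-length windows plus aligned per-sample targets.

    ``data`` has shape (n_segments, segment_length); ``targets`` is the same
    shape (binary).  ``provenance`` carries one ``(recording_id, start_index)``
    pair per segment.
    """

    data: np.ndarray
    targets: np.ndarray
    sampling_rate_hz: float
    provenance: list[tuple[str, int]]

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=np.float64))
        self.targets = np.atleast_2d(np.asarray(self.targets))
        if self.data.shape != self.targets.shape:
            raise ValueError("data and targets must have identical shapes")
        if len(self.provenance) != self.data.shape[0]:
            raise ValueError("one provenance entry per segment required")

    def __len__(self) -> int:
        return self.data.shape[0]

    @property
    def segment_length(self) -> int:
        return self.data.shape[1]


# ---------------------------------------------------------------------------
# file round-trips
# ---------------------------------------------------------------------------


def write_recording(rec: Recording, path: str | Path, format: str | None = None) -> Path:
    """Write a recording as headered CSV, EDF or binary (``.npy`` + JSON)."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "csv":
        _write_csv(rec, path)
    elif fmt == "edf":
        _write_edf(rec, path)
    elif fmt == "npy":
        _write_npy(rec, path)
    else:
        raise FormatError(f"unknown format {fmt!r}")
    return path


def read_recording(path: str | Path, format: str | None = None) -> Recording:
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "csv":
        return _read_csv(path)
    if fmt == "edf":
        return _read_edf(path)
    if fmt == "npy":
        return _read_npy(path)
    raise FormatError(f"unknown format {fmt!r}")


def _infer_format(path: Path) -> str:
    ext = path.suffix.lower().lstrip(".")
    if ext in ("csv", "edf", "npy"):
        return ext
    raise FormatError(f"cannot infer format from {path.name!r}")


def _meta_str(meta: dict) -> str:
    return ";".join(f"{k}={v}" for k, v in meta.items())


def _parse_meta(s: str) -> dict:
    out = {}
    for part in s.split(";"):
        if part and "=" in part:
            k, v = part.split("=", 1)
            out[k] = v
    return out


def _write_csv(rec: Recording, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# sampling_rate_hz={rec.sampling_rate_hz!r}\n")
        fh.write(f"# recording_id={rec.recording_id};{_meta_str(rec.meta)}\n")
        np.savetxt(fh, rec.samples, fmt="%.10g")


def _read_csv(path: Path) -> Recording:
    with open(path) as fh:
        line1 = fh.readline().strip()
        line2 = fh.readline().strip()
        if not line1.startswith("# sampling_rate_hz="):
            raise FormatError("missing sampling-rate header line")
        try:
            rate = float(line1.split("=", 1)[1])
        except ValueError as exc:
            raise FormatError("unparseable sampling rate") from exc
        if rate <= 0:
            raise FormatError("sampling rate must be > 0")
        if not line2.startswith("# "):
            raise FormatError("missing metadata header line")
        meta = _parse_meta(line2[2:])
        rec_id = meta.pop("recording_id", "rec")
        samples = np.loadtxt(fh, ndmin=1)
    return Recording(samples, rate, rec_id, meta)


# -- EDF: minimal single-channel implementation (16-bit, 1-s data records) --


def _write_edf(rec: Recording, path: Path) -> None:
    rate = rec.sampling_rate_hz
    spr = int(round(rate))
    if abs(spr - rate) > 1e-9 or spr <= 0:
        raise FormatError("EDF export requires an integer sampling rate")
    x = rec.samples
    n_rec = int(np.ceil(x.size / spr))
    pad = n_rec * spr - x.size
    if pad:
        x = np.concatenate([x, np.full(pad, x[-1])])
    pmin, pmax = float(x.min()), float(x.max())
    if pmax <= pmin:
        pmax = pmin + 1.0
    dmin, dmax = -32768, 32767
    scale = (pmax - pmin) / (dmax - dmin)
    dig = np.round((x - pmin) / scale + dmin).astype("<i2")

    def f(v: object, n: int) -> bytes:
        s = str(v)[:n]
        return s.ljust(n).encode("ascii")

    hdr = b"".join(
        [
            f("0", 8),
            f(f"{rec.recording_id} {_meta_str(rec.meta)}", 80),
            f("Startdate X X X X", 80),
            f("01.01.00", 8),
            f("00.00.00", 8),
            f(512, 8),  # header bytes: 256 + 1 signal * 256
            f("EDF", 44),
            f(n_rec, 8),
            f(1, 8),  # record duration 1 s
            f(1, 4),  # one signal
            # per-signal fields
            f("LFP", 16),
            f("AgAgCl electrode", 80),
            f("uV", 8),
            f(f"{pmin:.6g}", 8),
            f(f"{pmax:.6g}", 8),
            f(dmin, 8),
            f(dmax, 8),
            f("LP:30Hz", 80),
            f(spr, 8),
            f("", 32),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(hdr)
        fh.write(dig.tobytes())
    side = path.with_suffix(path.suffix + ".json")
    side.write_text(json.dumps({"n_samples": rec.n_samples}))


def _read_edf(path: Path) -> Recording:
    with open(path, "rb") as fh:
        hdr = fh.read(256)
        if len(hdr) < 256:
            raise FormatError("truncated EDF header")
        n_rec = int(hdr[236:244].decode().strip())
        rec_dur = float(hdr[244:252].decode().strip())
        ns = int(hdr[252:256].decode().strip())
        if ns != 1:
            raise FormatError("only single-channel EDF supported")
        sig = fh.read(256 * ns)
        pmin = float(sig[16 * ns + 80 * ns + 8 * ns : 16 * ns + 80 * ns + 8 * ns + 8].decode())
        pmax = float(sig[16 * ns + 80 * ns + 8 * ns + 8 : 16 * ns + 80 * ns + 8 * ns + 16].decode())
        off = 16 * ns + 80 * ns + 8 * ns + 16
        dmin = int(sig[off : off + 8].decode().strip())
        dmax = int(sig[off + 8 : off + 16].decode().strip())
        spr = int(sig[off + 16 + 80 : off + 16 + 80 + 8].decode().strip())
        label_field = hdr[8:88].decode().strip()
        dig = np.frombuffer(fh.read(2 * spr * n_rec), dtype="<i2").astype(np.float64)
    scale = (pmax - pmin) / (dmax - dmin)
    x = (dig - dmin) * scale + pmin
    rate = spr / rec_dur
    side = path.with_suffix(path.suffix + ".json")
    if side.exists():
        n = json.loads(side.read_text()).get("n_samples", x.size)
        x = x[:n]
    parts = label_field.split(" ", 1)
    rec_id = parts[0] if parts else "rec"
    meta = _parse_meta(parts[1]) if len(parts) > 1 else {}
    return Recording(x, rate, rec_id, meta)


def _write_npy(rec: Recording, path: Path) -> None:
    np.save(path, rec.samples.astype(np.float32))
    side = path.with_suffix(".json")
    side.write_text(
        json.dumps(
            {
                "sampling_rate_hz": rec.sampling_rate_hz,
                "recording_id": rec.recording_id,
                "meta": rec.meta,
            }
        )
    )


def _read_npy(path: Path) -> Recording:
    x = np.load(path).astype(np.float64)
    side = path.with_suffix(".json")
    if not side.exists():
        raise FormatError(f"missing JSON sidecar for {path.name}")
    info = json.loads(side.read_text())
    return Recording(x, info["sampling_rate_hz"], info.get("recording_id", "rec"), info.get("meta", {}))


def write_events(events: EventList, path: str | Path) -> Path:
    """Write events as ``onset_s<TAB>offset_s`` lines (manual-review format)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# sampling_rate_hz={events.sampling_rate_hz!r}\ttotal_window_s={events.total_window_s!r}\n")
        for e in events:
            fh.write(f"{e.onset / events.sampling_rate_hz:.6f}\t{e.offset / events.sampling_rate_hz:.6f}\n")
    return path


def read_events(path: str | Path, sampling_rate_hz: float | None = None, total_window_s: float | None = None) -> EventList:
    path = Path(path)
    rate, window = sampling_rate_hz, total_window_s
    evs: list[Event] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                hdr = _parse_meta(line[1:].strip().replace("\t", ";"))
                rate = rate or float(hdr.get("sampling_rate_hz", 0)) or None
                window = window or float(hdr.get("total_window_s", 0)) or None
                continue
            on_s, off_s = map(float, line.split("\t"))
            if rate is None:
                raise FormatError("sampling rate neither in header nor given")
            evs.append(Event(int(round(on_s * rate)), int(round(off_s * rate))))
    if rate is None or window is None:
        raise FormatError("event file lacks rate/window header")
    return EventList(evs, rate, window)


# ---------------------------------------------------------------------------
# windowing / resampling / segmentation
# ---------------------------------------------------------------------------


def select_analysis_window(rec: Recording, start_min: float, end_min: float) -> Recording:
    """Half-open time slice ``[start_min, end_min)`` of a recording.

    The experimental protocol analyzes minutes 100-140 of each recording;
    callers pass those bounds explicitly.
    """
    if not 0 <= start_min < end_min:
        raise ValueError("need 0 <= start < end")
    i0 = int(round(start_min * 60 * rec.sampling_rate_hz))
    i1 = int(round(end_min * 60 * rec.sampling_rate_hz))
    if i1 > rec.n_samples:
        raise ValueError("window extends beyond recording")
    return rec.copy_with(samples=rec.samples[i0:i1].copy())


def downsample(rec: Recording, target_rate_hz: float = 125.0) -> Recording:
    """Anti-aliased decimation to ``target_rate_hz``.

    A zero-phase Butterworth low-pass at 0.4 x target rate precedes the
    decimation so that in-band content (e.g. a 10-Hz tone) survives with
    < 5 % amplitude loss while aliasing is suppressed.
    """
    if target_rate_hz > rec.sampling_rate_hz:
        raise ValueError("target rate exceeds original rate")
    if target_rate_hz == rec.sampling_rate_hz:
        return rec
    ratio = rec.sampling_rate_hz / target_rate_hz
    q = int(round(ratio))
    sos = sps.butter(8, 0.4 * target_rate_hz, fs=rec.sampling_rate_hz, output="sos")
    filtered = sps.sosfiltfilt(sos, rec.samples)
    if abs(ratio - q) < 1e-9:
        out = filtered[::q]
    else:  # rational but non-integer ratio
        from fractions import Fraction

        fr = Fraction(target_rate_hz / rec.sampling_rate_hz).limit_denominator(10_000)
        out = sps.resample_poly(filtered, fr.numerator, fr.denominator)
    n_out = int(np.floor(rec.n_samples * target_rate_hz / rec.sampling_rate_hz))
    out = out[:n_out]
    return rec.copy_with(samples=np.ascontiguousarray(out), sampling_rate_hz=target_rate_hz)


def segment(rec: Recording, labels: LabelSeries, window_s: float = 30.0) -> SegmentBatch:
    """Tile a labeled recording into non-overlapping ``window_s`` windows.

    The trailing remainder shorter than one window is dropped.
    """
    if len(labels) != rec.n_samples:
        raise ValueError("label series not aligned to recording")
    if abs(labels.sampling_rate_hz - rec.sampling_rate_hz) > 1e-9:
        raise ValueError("label rate differs from recording rate")
    L = int(round(window_s * rec.sampling_rate_hz))
    n = rec.n_samples // L
    if n == 0:
        return SegmentBatch(
            np.empty((0, L)), np.empty((0, L), dtype=np.uint8), rec.sampling_rate_hz, []
        )
    data = rec.samples[: n * L].reshape(n, L).copy()
    targ = labels.labels[: n * L].reshape(n, L).copy()
    prov = [(rec.recording_id, i * L) for i in range(n)]
    return SegmentBatch(data, targ, rec.sampling_rate_hz, prov)


def standardize_segment(seg: np.ndarray) -> np.ndarray:
    """Subtract the mean and divide by the population standard deviation.

    Constant (dead-channel) segments map to all-zeros with a logged warning
    instead of erroring, so batch preparation never aborts.
    """
    seg = np.asarray(seg, dtype=np.float64)
    if seg.shape[-1] < 2:
        raise ValueError("segment too short to standardize")
    mu = seg.mean(axis=-1, keepdims=True)
    sd = seg.std(axis=-1, keepdims=True)  # population (divide-by-n) convention
    out = np.zeros_like(seg)
    ok = (sd > 0).squeeze()
    if seg.ndim == 1:
        if sd[0] > 0:
            out = (seg - mu) / sd
        else:
            logger.warning("constant segment standardized to zeros")
    else:
        if not np.all(ok):
            logger.warning("%d constant segment(s) standardized to zeros", int((~ok).sum()))
        nz = np.where(ok)[0]
        out[nz] = (seg[nz] - mu[nz]) / sd[nz]
    return out
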