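"""Core data model for timestamped multimodal streams and session bundles.

A recording session in an instrumented gait lab consists of several
independently clocked acquisition devices (force plates, EMG, EEG, fNIRS,
photodiode channel).  Each device contributes a :class:`TimestampedStream`
(regularly sampled data with per-sample timestamps on a named local clock)
and possibly :class:`MarkerEvent` entries (byte-coded events).  A
:class:`StreamBundle` collects everything belonging to one session together
with free-form metadata (simulator ground truth, configuration hashes).

On-disk format: one delimited CSV file per stream (first column the
timestamp, then one column per channel) plus a single JSON manifest that
records names, rates, units, clocks, events and metadata.  Timestamps are
written with full double precision (sub-millisecond accuracy over hours of
recording requires it); sample values are written with single-precision
significance, which dominates nothing downstream.
"""

from __future__ import annotations

import io
import json
import logging
import math
import struct
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger("gaitsync")

MANIFEST_NAME = "manifest.json"
MANIFEST_VERSION = 1

#: Recognized stream modalities.
MODALITIES = (
    "eeg",
    "emg",
    "cop",
    "fnirs_intensity",
    "fnirs_hemo",
    "photodiode_analog",
    "photodiode_digital",
)

#: Recognized marker-event provenances.
EVENT_SOURCES = ("command", "photodiode_decoded", "derived_onset")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class TimestampedStream:
    """One modality's samples with per-sample timestamps on a local clock.

    Parameters
    ----------
    name : str
        Unique stream name within a bundle.
    modality : str
        One of :data:`MODALITIES`.
    channel_labels : list of str
        One label per channel.
    units : list of str
        Per-channel unit string (e.g. ``µV``, ``mm``, ``V``, ``µM``).
    nominal_rate : float
        Nominal sampling rate in Hz.
    samples : ndarray, shape (n_samples, n_channels)
    timestamps : ndarray, shape (n_samples,)
        Seconds on the stream's local clock, strictly increasing.
    clock_id : str
        Name of the local clock the timestamps live on.
    """

    name: str
    modality: str
    channel_labels: list[str]
    units: list[str]
    nominal_rate: float
    samples: np.ndarray
    timestamps: np.ndarray
    clock_id: str

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.samples.shape[0] == 1 and len(np.asarray(self.timestamps)) > 1:
            self.samples = self.samples.T
        self.timestamps = np.asarray(self.timestamps, dtype=float)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    def channel(self, label: str) -> np.ndarray:
        """Return the 1-D data of the channel called *label*."""
        return self.samples[:, self.channel_labels.index(label)]

    def copy(self) -> "TimestampedStream":
        return replace(
            self,
            channel_labels=list(self.channel_labels),
            units=list(self.units),
            samples=self.samples.copy(),
            timestamps=self.timestamps.copy(),
        )


@dataclass
class MarkerEvent:
    """A byte-coded event at a point in time on a named clock.

    ``source`` records provenance: ``command`` for software-issued events,
    ``photodiode_decoded`` for events recovered from the photodiode trace,
    ``derived_onset`` for movement onsets computed from the data.
    """

    code: int
    time: float
    clock_id: str
    source: str = "command"

    def shifted(self, dt: float) -> "MarkerEvent":
        return replace(self, time=self.time + dt)


@dataclass
class StreamBundle:
    """A session container: streams + events + free-form metadata."""

    streams: list[TimestampedStream] = field(default_factory=list)
    events: list[MarkerEvent] = field(default_factory=list)
    metadata: dict[str, Any] = field(default_factory=dict)

    def stream(self, name: str) -> TimestampedStream:
        for s in self.streams:
            if s.name == name:
                return s
        raise KeyError(f"no stream named {name!r}")

    def events_from(self, source: str) -> list[MarkerEvent]:
        return [e for e in self.events if e.source == source]

    @property
    def clock_ids(self) -> set[str]:
        ids = {s.clock_id for s in self.streams}
        ids |= set(self.metadata.get("clocks", []))
        return ids


@dataclass
class EpochSet:
    """Event-locked trial x time x channel array.

    Excluded trials remain stored: exclusion is a flag (``qc_excluded``),
    never deletion, so that quality control stays auditable.
    """

    data: np.ndarray  # (n_trials, n_times, n_channels)
    times: np.ndarray  # seconds relative to the locking event
    channel_labels: list[str]
    baseline_window: tuple[float, float]
    event_codes: np.ndarray
    qc_excluded: np.ndarray  # bool per trial

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def included(self) -> np.ndarray:
        """Data of non-excluded trials."""
        return self.data[~self.qc_excluded]


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def validate_bundle(bundle: StreamBundle) -> list[str]:
    """Check every type invariant; return human-readable violations.

    The validator is total: it reports problems as strings and never raises,
    whatever the field values are.
    """
    out: list[str] = []
    try:
        seen: set[str] = set()
        for s in bundle.streams:
            out.extend(_validate_stream(s))
            if s.name in seen:
                out.append(f"stream {s.name!r}: duplicate stream name")
            seen.add(s.name)
        clock_ids = bundle.clock_ids
        for i, e in enumerate(bundle.events):
            prefix = f"event[{i}] (code={e.code!r})"
            if not (isinstance(e.code, (int, np.integer)) and 0 <= e.code <= 255):
                out.append(f"{prefix}: code must be an integer in 0..255")
            if not (isinstance(e.time, (int, float, np.floating)) and math.isfinite(e.time)):
                out.append(f"{prefix}: time must be finite")
            if e.source not in EVENT_SOURCES:
                out.append(f"{prefix}: unknown source {e.source!r}")
            if clock_ids and e.clock_id not in clock_ids:
                out.append(f"{prefix}: clock_id {e.clock_id!r} not among declared clocks")
    except Exception as exc:  # pragma: no cover - totality guard
        out.append(f"validation aborted: {exc!r}")
    return out


def _validate_stream(s: TimestampedStream) -> list[str]:
    out: list[str] = []
    name = s.name
    if s.modality not in MODALITIES:
        out.append(f"stream {name!r}: unknown modality {s.modality!r}")
    if len(s.timestamps) != s.n_samples:
        out.append(f"stream {name!r}: len(timestamps) != n_samples")
    if not (len(s.channel_labels) == s.n_channels == len(s.units)):
        out.append(
            f"stream {name!r}: channel_labels/units/sample columns disagree "
            f"({len(s.channel_labels)}/{len(s.units)}/{s.n_channels})"
        )
    if not (np.isscalar(s.nominal_rate) and s.nominal_rate > 0):
        out.append(f"stream {name!r}: nominal_rate must be > 0")
        return out
    if len(s.timestamps) > 1:
        dt = np.diff(s.timestamps)
        if not np.all(dt > 0):
            out.append(f"stream {name!r}: timestamps not strictly increasing")
        else:
            med = float(np.median(dt))
            if abs(med - 1.0 / s.nominal_rate) > 0.1 / s.nominal_rate:
                out.append(
                    f"stream {name!r}: median timestamp increment {med:.6g} s "
                    f"deviates > 10% from 1/nominal_rate"
                )
    return out


# ---------------------------------------------------------------------------
# Bundle CSV + manifest I/O
# ---------------------------------------------------------------------------


def write_bundle(bundle: StreamBundle, path: str | Path) -> Path:
    """Write *bundle* as one CSV per stream plus a JSON manifest.

    Returns the manifest path.  Timestamps are written with 17 significant
    digits (lossless for doubles); samples with 9 (single-precision
    significance, per the on-disk width contract).
    """
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "format": "gaitsync-bundle",
        "version": MANIFEST_VERSION,
        "streams": [],
        "events": [
            {"code": int(e.code), "time": float(e.time), "clock_id": e.clock_id, "source": e.source}
            for e in bundle.events
        ],
        "metadata": _jsonable(bundle.metadata),
    }
    for s in bundle.streams:
        fname = f"{s.name}.csv"
        cols = {"timestamp": s.timestamps}
        for j, lab in enumerate(s.channel_labels):
            cols[lab] = s.samples[:, j]
        df = pd.DataFrame(cols)
        with open(root / fname, "w", newline="") as fh:
            fh.write("timestamp," + ",".join(s.channel_labels) + "\n")
            fmt = "%.17g," + ",".join(["%.9g"] * s.n_channels) + "\n"
            for row in df.itertuples(index=False):
                fh.write(fmt % tuple(row))
        manifest["streams"].append(
            {
                "name": s.name,
                "file": fname,
                "modality": s.modality,
                "channel_labels": list(s.channel_labels),
                "units": list(s.units),
                "nominal_rate": float(s.nominal_rate),
                "clock_id": s.clock_id,
            }
        )
    mpath = root / MANIFEST_NAME
    mpath.write_text(json.dumps(manifest, indent=1))
    return mpath


def read_bundle(path: str | Path) -> StreamBundle:
    """Read a bundle written by :func:`write_bundle`.

    Raises
    ------
    FileNotFoundError
        If the manifest is missing.
    ValueError
        If a stream file's channel count disagrees with the manifest.
    """
    root = Path(path)
    if root.name == MANIFEST_NAME:
        root = root.parent
    mpath = root / MANIFEST_NAME
    if not mpath.exists():
        raise FileNotFoundError(f"bundle manifest not found: {mpath}")
    manifest = json.loads(mpath.read_text())
    streams: list[TimestampedStream] = []
    for entry in manifest["streams"]:
        df = pd.read_csv(root / entry["file"], float_precision="round_trip")
        labels = entry["channel_labels"]
        if df.shape[1] - 1 != len(labels):
            raise ValueError(
                f"stream {entry['name']!r}: manifest lists {len(labels)} channels, "
                f"file has {df.shape[1] - 1}"
            )
        streams.append(
            TimestampedStream(
                name=entry["name"],
                modality=entry["modality"],
                channel_labels=labels,
                units=entry["units"],
                nominal_rate=entry["nominal_rate"],
                samples=df.iloc[:, 1:].to_numpy(float),
                timestamps=df.iloc[:, 0].to_numpy(float),
                clock_id=entry["clock_id"],
            )
        )
    events = [
        MarkerEvent(code=e["code"], time=e["time"], clock_id=e["clock_id"], source=e["source"])
        for e in manifest["events"]
    ]
    return StreamBundle(streams=streams, events=events, metadata=manifest.get("metadata", {}))


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


# ---------------------------------------------------------------------------
# Minimal XDF reading
# ---------------------------------------------------------------------------
#
# XDF is the container written by LSL's LabRecorder: a "XDF:" magic string
# followed by length-prefixed chunks.  Only the subset needed to import
# numeric streams and string marker streams is implemented here; there is
# deliberately no write support.

_XDF_FMT = {
    "float32": ("<f", 4),
    "double64": ("<d", 8),
    "int8": ("<b", 1),
    "int16": ("<h", 2),
    "int32": ("<i", 4),
    "int64": ("<q", 8),
}


def read_xdf_subset(path: str | Path) -> StreamBundle:
    """Read an XDF file into a :class:`StreamBundle`.

    Numeric streams become :class:`TimestampedStream`; string marker streams
    become :class:`MarkerEvent` lists (the label parsed as an integer byte;
    non-integer labels are hashed into 0..255 with a warning).  Streams with
    an unsupported channel format are skipped with a log entry.  Timestamps
    absent from a sample are deduced from the previous timestamp and the
    nominal rate, as LabRecorder intends.
    """
    raw = Path(path).read_bytes()
    if raw[:4] != b"XDF:":
        raise ValueError(f"{path}: not an XDF file (bad magic bytes)")
    buf = io.BytesIO(raw)
    buf.seek(4)

    headers: dict[int, dict[str, Any]] = {}
    chunks: dict[int, list[tuple[np.ndarray, list]]] = {}

    while True:
        nbytes = buf.read(1)
        if not nbytes:
            break
        n = nbytes[0]
        if n == 1:
            length = buf.read(1)[0]
        elif n == 4:
            length = struct.unpack("<I", buf.read(4))[0]
        elif n == 8:
            length = struct.unpack("<Q", buf.read(8))[0]
        else:
            raise ValueError(f"{path}: corrupt chunk length field ({n})")
        body = buf.read(length)
        if len(body) < length:
            raise ValueError(f"{path}: truncated chunk")
        tag = struct.unpack("<H", body[:2])[0]
        content = body[2:]
        if tag == 2:  # StreamHeader
            sid = struct.unpack("<I", content[:4])[0]
            headers[sid] = _parse_xdf_header(content[4:].decode("utf-8", "replace"))
            chunks[sid] = []
        elif tag == 3:  # Samples
            sid = struct.unpack("<I", content[:4])[0]
            if sid not in headers:
                raise ValueError(f"{path}: samples for undeclared stream {sid}")
            try:
                chunks[sid].append(_parse_xdf_samples(content[4:], headers[sid]))
            except _UnsupportedFormat as exc:
                logger.warning("stream %s: %s; skipped", headers[sid].get("name"), exc)
                headers[sid]["skip"] = True
        # tags 1 (FileHeader), 4 (ClockOffset), 5 (Boundary), 6 (Footer): ignored

    bundle = StreamBundle()
    for sid, hdr in headers.items():
        if hdr.get("skip"):
            continue
        ts_parts, val_parts = [], []
        for ts, vals in chunks[sid]:
            ts_parts.append(ts)
            val_parts.extend(vals)
        ts = _fill_xdf_timestamps(
            np.concatenate(ts_parts) if ts_parts else np.empty(0), hdr["srate"]
        )
        if hdr["format"] == "string":
            for t, label in zip(ts, val_parts):
                bundle.events.append(
                    MarkerEvent(code=_marker_code(label), time=float(t),
                                clock_id="xdf", source="command")
                )
        else:
            samples = np.asarray(val_parts, dtype=float).reshape(-1, hdr["channel_count"])
            rate = hdr["srate"] if hdr["srate"] > 0 else _infer_rate(ts)
            bundle.streams.append(
                TimestampedStream(
                    name=hdr["name"],
                    modality=hdr.get("modality", "eeg"),
                    channel_labels=[f"ch{i}" for i in range(hdr["channel_count"])],
                    units=["unknown"] * hdr["channel_count"],
                    nominal_rate=rate,
                    samples=samples,
                    timestamps=ts,
                    clock_id="xdf",
                )
            )
    bundle.metadata["source"] = str(path)
    bundle.metadata["clocks"] = ["xdf"]
    return bundle


class _UnsupportedFormat(Exception):
    pass


def _parse_xdf_header(xml: str) -> dict[str, Any]:
    import xml.etree.ElementTree as ET

    root = ET.fromstring(xml)

    def text(tag: str, default: str = "") -> str:
        el = root.find(tag)
        return el.text if el is not None and el.text else default

    fmt = text("channel_format", "float32")
    type_ = text("type", "").lower()
    modality = type_ if type_ in MODALITIES else "eeg"
    return {
        "name": text("name", "xdf_stream"),
        "channel_count": int(text("channel_count", "1")),
        "srate": float(text("nominal_srate", "0")),
        "format": fmt,
        "modality": modality,
    }


def _parse_xdf_samples(content: bytes, hdr: dict[str, Any]) -> tuple[np.ndarray, list]:
    buf = io.BytesIO(content)
    n = buf.read(1)[0]
    if n == 1:
        count = buf.read(1)[0]
    elif n == 4:
        count = struct.unpack("<I", buf.read(4))[0]
    elif n == 8:
        count = struct.unpack("<Q", buf.read(8))[0]
    else:
        raise ValueError("corrupt sample-count field")
    fmt = hdr["format"]
    nchan = hdr["channel_count"]
    ts = np.full(count, np.nan)
    values: list = []
    for i in range(count):
        tbytes = buf.read(1)[0]
        if tbytes == 8:
            ts[i] = struct.unpack("<d", buf.read(8))[0]
        elif tbytes != 0:
            raise ValueError("corrupt timestamp-byte marker")
        if fmt == "string":
            slen_b = buf.read(1)[0]
            if slen_b == 1:
                slen = buf.read(1)[0]
            elif slen_b == 4:
                slen = struct.unpack("<I", buf.read(4))[0]
            else:
                slen = struct.unpack("<Q", buf.read(8))[0]
            values.append(buf.read(slen).decode("utf-8", "replace"))
        elif fmt in _XDF_FMT:
            code, size = _XDF_FMT[fmt]
            row = struct.unpack("<" + code[1] * nchan, buf.read(size * nchan))
            values.append(row)
        else:
            raise _UnsupportedFormat(f"unsupported channel format {fmt!r}")
    return ts, values


def _fill_xdf_timestamps(ts: np.ndarray, srate: float) -> np.ndarray:
    dt = 1.0 / srate if srate > 0 else 0.0
    out = ts.copy()
    last = 0.0
    for i in range(len(out)):
        if np.isnan(out[i]):
            out[i] = last + dt
        last = out[i]
    return out


def _infer_rate(ts: np.ndarray) -> float:
    if len(ts) > 1:
        d = np.median(np.diff(ts))
        if d > 0:
            return 1.0 / float(d)
    return 1.0


def _marker_code(label: str) -> int:
    try:
        code = int(label.strip())
        if 0 <= code <= 255:
            return code
    except ValueError:
        pass
    warnings.warn(f"marker label {label!r} is not a byte; hashing into 0..255")
    return hash(label) % 256
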