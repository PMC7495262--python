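"""Timestamped multi-rate biosignal streams, event annotations and sessions.

Every stream carries its own UTC start time and sampling rate; nothing in the
package ever aligns streams by array index.  Sample ``k`` of a stream is
located at ``start_utc + k / rate`` and all windowing uses half-open UTC
intervals ``[start, end)``, which makes slicing at any ordered set of
boundaries an exact partition of the samples (no loss, no duplication).

On-disk formats are deliberately plain text so fixtures stay human-auditable:

* stream CSV — ``#key=value`` header lines (modality, channel, rate,
  start_utc, units) followed by one sample per line;
* annotation CSV — ``time_utc,label,kind`` rows, sorted ascending;
* session manifest — YAML/JSON mapping a participant/group/session to its
  stream files and annotation file.

An additional reader for the wristband-style CSV layout (first row = epoch
start, second row = rate, then samples) is provided as a dialect.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .errors import FormatError, IntegrityError

__all__ = [
    "MODALITIES",
    "MODALITY_UNITS",
    "DEFAULT_RATES",
    "ANNOTATION_KINDS",
    "GROUPS",
    "SESSION_KINDS",
    "BiosignalStream",
    "EventAnnotation",
    "SessionRecording",
    "read_stream",
    "write_stream",
    "read_empatica_stream",
    "read_annotations",
    "write_annotations",
    "slice_stream",
    "read_session",
    "write_session",
]

MODALITY_UNITS = {"EEG": "uV", "HR": "bpm", "EDA": "uS"}
MODALITIES = tuple(MODALITY_UNITS)
#: Acquisition rates of the recording rig: 256 Hz EEG amplifier, 1 Hz heart
#: rate and 4 Hz electrodermal activity from the wrist wearable.
DEFAULT_RATES = {"EEG": 256.0, "HR": 1.0, "EDA": 4.0}
ANNOTATION_KINDS = ("node_transition", "gesture", "session_start", "session_end")
#: Kinds that mark a scenario event and therefore a segment boundary.
EVENT_KINDS = ("node_transition", "gesture")
GROUPS = ("student", "postgraduate", "neurosurgeon")
SESSION_KINDS = ("VP_baseline", "MR")

# Tolerance (in fractional samples) when mapping UTC instants to indices, so
# that boundaries that are exact sample times are not lost to float rounding.
_EPS_SAMPLES = 1e-6


@dataclass(frozen=True)
class BiosignalStream:
    """One modality's uniformly sampled series on the shared UTC clock.

    Parameters
    ----------
    modality : {"EEG", "HR", "EDA"}
    channel : str
        Channel label, e.g. ``"Cz"`` for EEG, ``"wrist"`` for the wearable.
    rate : float
        Sampling rate in samples/s.
    start_utc : float
        UTC epoch seconds of sample 0 (fractional allowed).
    samples : numpy.ndarray
        Sample values in the modality's units (uV, bpm, uS).
    """

    modality: str
    channel: str
    rate: float
    start_utc: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        if self.modality not in MODALITY_UNITS:
            raise IntegrityError(f"unknown modality {self.modality!r}")
        if not self.rate > 0:
            raise IntegrityError("rate must be > 0")
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size == 0:
            raise IntegrityError("samples must be a non-empty 1-D array")
        object.__setattr__(self, "samples", samples)

    @property
    def units(self) -> str:
        return MODALITY_UNITS[self.modality]

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate

    @property
    def end_utc(self) -> float:
        """UTC instant just past the final sample (half-open span end)."""
        return self.start_utc + self.n_samples / self.rate

    def times(self) -> np.ndarray:
        """UTC timestamp of every sample."""
        return self.start_utc + np.arange(self.n_samples) / self.rate


@dataclass(frozen=True, order=True)
class EventAnnotation:
    """A UTC-stamped scenario event (segment boundary or session marker)."""

    time_utc: float
    label: str = field(compare=False)
    kind: str = field(compare=False)

    def __post_init__(self) -> None:
        if self.kind not in ANNOTATION_KINDS:
            raise FormatError(f"unknown annotation kind {self.kind!r}")


@dataclass
class SessionRecording:
    """All streams and annotations of one participant x session.

    ``session_kind`` distinguishes the web-based virtual-patient baseline
    session from the mixed-reality session.
    """

    participant_id: str
    group: str
    session_kind: str
    streams: list[BiosignalStream]
    annotations: list[EventAnnotation]

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise IntegrityError(f"unknown group {self.group!r}")
        if self.session_kind not in SESSION_KINDS:
            raise IntegrityError(f"unknown session kind {self.session_kind!r}")
        keys = [(s.modality, s.channel) for s in self.streams]
        if len(set(keys)) != len(keys):
            raise IntegrityError("duplicate (modality, channel) stream")

    def get_stream(self, modality: str, channel: str | None = None) -> BiosignalStream:
        hits = [
            s
            for s in self.streams
            if s.modality == modality and (channel is None or s.channel == channel)
        ]
        if not hits:
            raise IntegrityError(f"no {modality} stream" + (f" on {channel}" if channel else ""))
        if len(hits) > 1:
            raise IntegrityError(f"ambiguous {modality} stream; specify channel")
        return hits[0]

    def span(self) -> tuple[float, float]:
        """Intersection of all stream spans — the only window where every
        modality has data, hence the span used for segmentation."""
        start = max(s.start_utc for s in self.streams)
        end = min(s.end_utc for s in self.streams)
        if not start < end:
            raise IntegrityError("streams do not overlap in time")
        return start, end


# ---------------------------------------------------------------------------
# stream CSV dialect


def write_stream(stream: BiosignalStream, path: str | Path) -> None:
    """Write a stream in the ``#key=value`` header CSV dialect (lossless)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"#modality={stream.modality}\n")
        fh.write(f"#channel={stream.channel}\n")
        fh.write(f"#rate={stream.rate!r}\n")
        fh.write(f"#start_utc={stream.start_utc!r}\n")
        fh.write(f"#units={stream.units}\n")
        for v in stream.samples:
            fh.write(f"{float(v)!r}\n")


def read_stream(
    path: str | Path,
    modality: str | None = None,
    expected_rate: float | None = None,
) -> BiosignalStream:
    """Read a stream CSV.

    Parameters
    ----------
    modality : str, optional
        If given, the file's modality header must match.
    expected_rate : float, optional
        Rate the file must declare.  Defaults to the modality's acquisition
        rate (256 / 1 / 4 samples/s); pass explicitly to accept a
        non-standard rig, e.g. when a manifest overrides it.
    """
    path = Path(path)
    header: dict[str, str] = {}
    values: list[float] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "=" not in line:
                    raise FormatError(f"{path}:{lineno}: malformed header line {line!r}")
                key, _, val = line[1:].partition("=")
                header[key.strip()] = val.strip()
            else:
                try:
                    values.append(float(line))
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: bad sample {line!r}") from exc
    missing = {"modality", "channel", "rate", "start_utc"} - header.keys()
    if missing:
        raise FormatError(f"{path}: missing header fields {sorted(missing)}")
    if not values:
        raise FormatError(f"{path}: empty samples section")
    file_modality = header["modality"]
    if modality is not None and file_modality != modality:
        raise FormatError(f"{path}: modality {file_modality!r}, expected {modality!r}")
    rate = float(header["rate"])
    expected = expected_rate if expected_rate is not None else DEFAULT_RATES.get(file_modality)
    if expected is not None and not math.isclose(rate, expected, rel_tol=1e-9):
        raise IntegrityError(
            f"{path}: rate {rate} inconsistent with expected {expected} for {file_modality}"
        )
    units = header.get("units")
    if units is not None and units != MODALITY_UNITS.get(file_modality):
        raise IntegrityError(f"{path}: units {units!r} do not match modality {file_modality!r}")
    return BiosignalStream(
        modality=file_modality,
        channel=header["channel"],
        rate=rate,
        start_utc=float(header["start_utc"]),
        samples=np.asarray(values),
    )


def read_empatica_stream(
    path: str | Path, modality: str, channel: str = "wrist"
) -> BiosignalStream:
    """Read the wristband CSV dialect: row 1 = UTC epoch start, row 2 = rate,
    remaining rows = samples."""
    path = Path(path)
    with path.open() as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if len(lines) < 3:
        raise FormatError(f"{path}: need start row, rate row and >=1 sample")
    try:
        start_utc = float(lines[0].split(",")[0])
        rate = float(lines[1].split(",")[0])
        samples = np.asarray([float(ln.split(",")[0]) for ln in lines[2:]])
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric field") from exc
    return BiosignalStream(modality, channel, rate, start_utc, samples)


# ---------------------------------------------------------------------------
# annotations


def write_annotations(annotations: Sequence[EventAnnotation], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("time_utc,label,kind\n")
        for a in annotations:
            fh.write(f"{a.time_utc!r},{a.label},{a.kind}\n")


def read_annotations(path: str | Path) -> list[EventAnnotation]:
    """Read annotation CSV; returns annotations sorted ascending.

    Out-of-order rows are sorted with a warning; duplicate timestamps are an
    :class:`IntegrityError` (two scenario events cannot coincide).
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().strip().split(",")
        if header != ["time_utc", "label", "kind"]:
            raise FormatError(f"{path}: expected header time_utc,label,kind, got {header}")
        rows = []
        for lineno, raw in enumerate(fh, 2):
            line = raw.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 fields")
            try:
                t = float(parts[0])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad time {parts[0]!r}") from exc
            rows.append(EventAnnotation(t, parts[1], parts[2]))
    times = [a.time_utc for a in rows]
    if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
        if len(set(times)) != len(times):
            raise IntegrityError(f"{path}: duplicate annotation timestamps")
        warnings.warn(f"{path}: annotations out of order; sorting", stacklevel=2)
        rows.sort()
    elif len(set(times)) != len(times):  # pragma: no cover - caught above
        raise IntegrityError(f"{path}: duplicate annotation timestamps")
    return rows


# ---------------------------------------------------------------------------
# slicing


def _index_range(stream: BiosignalStream, start_utc: float, end_utc: float) -> tuple[int, int]:
    """Index range [lo, hi) of samples with timestamps in [start_utc, end_utc)."""
    lo = math.ceil((start_utc - stream.start_utc) * stream.rate - _EPS_SAMPLES)
    hi = math.ceil((end_utc - stream.start_utc) * stream.rate - _EPS_SAMPLES)
    return max(lo, 0), min(max(hi, 0), stream.n_samples)


def slice_stream(
    stream: BiosignalStream, start_utc: float, end_utc: float
) -> BiosignalStream | None:
    """Samples of ``stream`` in the half-open UTC window ``[start, end)``.

    Returns ``None`` when the window contains no sample (the caller decides
    whether an empty segment is an error).  Because the window is half-open
    and index mapping is shared between both ends, slicing at any ordered set
    of boundaries partitions the stream exactly.
    """
    if not start_utc < end_utc:
        raise IntegrityError("slice requires start_utc < end_utc")
    lo, hi = _index_range(stream, start_utc, end_utc)
    if hi <= lo:
        return None
    return replace(
        stream,
        start_utc=stream.start_utc + lo / stream.rate,
        samples=stream.samples[lo:hi],
    )


# ---------------------------------------------------------------------------
# session manifests


def write_session(recording: SessionRecording, out_dir: str | Path) -> Path:
    """Write all streams, the annotation file and a YAML manifest to a
    directory; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for s in recording.streams:
        fname = f"{s.modality.lower()}_{s.channel}.csv"
        write_stream(s, out_dir / fname)
        entries.append(
            {"modality": s.modality, "channel": s.channel, "rate": s.rate, "path": fname}
        )
    write_annotations(recording.annotations, out_dir / "annotations.csv")
    manifest = {
        "participant_id": recording.participant_id,
        "group": recording.group,
        "session_kind": recording.session_kind,
        "streams": entries,
        "annotations": "annotations.csv",
    }
    manifest_path = out_dir / "session.yaml"
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return manifest_path


def read_session(manifest_path: str | Path) -> SessionRecording:
    """Load a session from its YAML/JSON manifest.

    Stream rates declared in the manifest override the modality defaults, so
    a non-standard rig must be explicit in the manifest to be accepted.
    """
    manifest_path = Path(manifest_path)
    text = manifest_path.read_text()
    manifest = (
        json.loads(text) if manifest_path.suffix == ".json" else yaml.safe_load(text)
    )
    for key in ("participant_id", "group", "session_kind", "streams", "annotations"):
        if key not in manifest:
            raise FormatError(f"{manifest_path}: manifest missing {key!r}")
    base = manifest_path.parent
    streams = []
    for entry in manifest["streams"]:
        streams.append(
            read_stream(
                base / entry["path"],
                modality=entry.get("modality"),
                expected_rate=entry.get("rate"),
            )
        )
    annotations = read_annotations(base / manifest["annotations"])
    recording = SessionRecording(
        participant_id=str(manifest["participant_id"]),
        group=manifest["group"],
        session_kind=manifest["session_kind"],
        streams=streams,
        annotations=annotations,
    )
    lo, hi = recording.span()
    for a in annotations:
        if a.kind in EVENT_KINDS and not (lo <= a.time_utc < hi):
            warnings.warn(
                f"annotation {a.label!r} at {a.time_utc} outside joint stream span "
                f"[{lo}, {hi}); it will not bound any segment",
                stacklevel=2,
            )
    return recording
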