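"""Recording and annotation I/O, the 2-s segment grid, and ictal labeling.

Recordings are multichannel sampled signals in microvolts.  Annotations are
half-open ``[onset, offset)`` intervals in seconds from recording start.
A 2-s segment is labeled ICTAL when strictly more than 1 s of it lies inside
an annotated seizure, mirroring the visual-scoring convention the detector
is trained against.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import UnsupportedFormatError, ValidationError

SEGMENT_SECONDS = 2.0

__all__ = [
    "SEGMENT_SECONDS",
    "EEGRecording",
    "AnnotationTrack",
    "SegmentLabel",
    "LabeledSegment",
    "read_recording",
    "write_recording",
    "read_annotations",
    "write_annotations",
    "segment_recording",
    "label_segments",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class EEGRecording:
    """Multichannel EEG: ``samples`` is channels x time, in microvolts."""

    channel_names: list[str]
    sampling_rate: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be positive")
        if len(self.channel_names) == 0:
            raise ValidationError("recording must have at least one channel")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValidationError("channel names must be unique")
        if self.samples.ndim != 2 or self.samples.shape[0] != len(self.channel_names):
            raise ValidationError(
                "samples must be a 2-D channels x time array matching channel_names"
            )
        if not np.isfinite(self.samples).all():
            raise ValidationError("samples must be finite")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sampling_rate

    def channel(self, name: str) -> np.ndarray:
        return self.samples[self.channel_names.index(name)]


@dataclass(frozen=True)
class AnnotationTrack:
    """Normalized list of half-open seizure intervals, seconds from start.

    On construction the events are validated (onset < offset), sorted, and
    overlapping or touching intervals are merged, so labeling always works
    against a disjoint union.
    """

    events: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        norm = _normalize_intervals(self.events)
        object.__setattr__(self, "events", norm)

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def total_duration(self) -> float:
        """Summed seizure time in seconds."""
        return float(sum(off - on for on, off in self.events))

    def overlap(self, start: float, end: float) -> float:
        """Total intersection of ``[start, end)`` with the annotated union."""
        total = 0.0
        for on, off in self.events:
            total += max(0.0, min(off, end) - max(on, start))
        return total


def _normalize_intervals(
    events: Iterable[tuple[float, float]],
) -> tuple[tuple[float, float], ...]:
    cleaned = []
    for on, off in events:
        on = float(on)
        off = float(off)
        if not (on < off):
            raise ValidationError(f"interval onset must precede offset: ({on}, {off})")
        cleaned.append((on, off))
    cleaned.sort()
    merged: list[list[float]] = []
    for on, off in cleaned:
        if merged and on <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], off)
        else:
            merged.append([on, off])
    return tuple((a, b) for a, b in merged)


class SegmentLabel(str, Enum):
    ICTAL = "ICTAL"
    BASELINE = "BASELINE"
    UNLABELED = "UNLABELED"


@dataclass
class LabeledSegment:
    """One channel's 2-s window on the grid anchored at t = 0."""

    channel: str
    index: int
    samples: np.ndarray
    label: SegmentLabel = SegmentLabel.UNLABELED

    @property
    def t_start(self) -> float:
        return SEGMENT_SECONDS * self.index

    @property
    def t_end(self) -> float:
        return self.t_start + SEGMENT_SECONDS


# ---------------------------------------------------------------------------
# Recording I/O
# ---------------------------------------------------------------------------

def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.lower()
    suffix = path.suffix.lower().lstrip(".")
    return suffix or "edf"


def read_recording(
    path: str | Path,
    format: str | None = None,
    sampling_rate: float | None = None,
) -> EEGRecording:
    """Read an EEG recording from EDF or CSV.

    The CSV dialect is one header row of channel names followed by one row
    per sample; the sampling rate is not stored in the file and must be
    supplied (it is a sidecar field in pipeline configs).
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"recording file not found: {path}")
    fmt = _infer_format(path, format)
    if fmt == "edf":
        return _read_edf(path)
    if fmt == "csv":
        if sampling_rate is None:
            raise ValidationError("sampling_rate is required when reading CSV recordings")
        frame = pd.read_csv(path)
        if frame.shape[1] == 0 or frame.shape[0] == 0:
            raise ValidationError(f"CSV recording has no data: {path}")
        if frame.isna().any().any():
            raise ValidationError("CSV recording has missing values (unequal channel lengths?)")
        return EEGRecording(
            channel_names=[str(c) for c in frame.columns],
            sampling_rate=float(sampling_rate),
            samples=frame.to_numpy(dtype=float).T,
        )
    raise UnsupportedFormatError(f"unsupported recording format: {fmt!r}")


def write_recording(rec: EEGRecording, path: str | Path, format: str | None = None) -> None:
    """Write a recording to EDF (16-bit) or CSV (full precision)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "edf":
        _write_edf(rec, path)
    elif fmt == "csv":
        frame = pd.DataFrame(rec.samples.T, columns=rec.channel_names)
        frame.to_csv(path, index=False)
    else:
        raise UnsupportedFormatError(f"unsupported recording format: {fmt!r}")


def _read_edf(path: Path) -> EEGRecording:
    import mne  # heavy import; deferred

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data_uv = raw.get_data() * 1e6  # mne loads EDF in volts
    return EEGRecording(
        channel_names=list(raw.ch_names),
        sampling_rate=float(raw.info["sfreq"]),
        samples=data_uv,
    )


def _edf_field(value, width: int) -> bytes:
    text = str(value)
    if len(text) > width:
        text = text[:width]
    return text.ljust(width).encode("ascii")


def _write_edf(rec: EEGRecording, path: Path) -> None:
    """Minimal EDF writer: 1-s data records, 16-bit samples, 'uV' units.

    The final record is zero-padded when the duration is not a whole number
    of seconds, so read-back duration rounds up to the next second.
    """
    rate = rec.sampling_rate
    spr = rate  # samples per 1-s record
    if abs(spr - round(spr)) > 1e-9:
        raise ValidationError(
            "EDF writer uses 1-s records; sampling rate must be an integer Hz"
        )
    spr = int(round(spr))
    n_records = int(np.ceil(rec.n_samples / spr))
    ns = rec.n_channels

    # one symmetric physical range per channel, wide enough for the data
    phys_max = np.maximum(np.max(np.abs(rec.samples), axis=1), 1.0)
    phys_max = np.ceil(phys_max)
    dig_min, dig_max = -32768, 32767

    header = b"".join(
        [
            _edf_field("0", 8),
            _edf_field("ratseiz", 80),
            _edf_field("synthetic", 80),
            _edf_field("01.01.00", 8),
            _edf_field("00.00.00", 8),
            _edf_field(256 * (1 + ns), 8),
            _edf_field("", 44),
            _edf_field(n_records, 8),
            _edf_field("1", 8),
            _edf_field(ns, 4),
        ]
    )
    sig = b"".join(_edf_field(name, 16) for name in rec.channel_names)
    sig += b"".join(_edf_field("", 80) for _ in range(ns))
    sig += b"".join(_edf_field("uV", 8) for _ in range(ns))
    sig += b"".join(_edf_field(f"{-pm:g}", 8) for pm in phys_max)
    sig += b"".join(_edf_field(f"{pm:g}", 8) for pm in phys_max)
    sig += b"".join(_edf_field(dig_min, 8) for _ in range(ns))
    sig += b"".join(_edf_field(dig_max, 8) for _ in range(ns))
    sig += b"".join(_edf_field("", 80) for _ in range(ns))
    sig += b"".join(_edf_field(spr, 8) for _ in range(ns))
    sig += b"".join(_edf_field("", 32) for _ in range(ns))

    padded = np.zeros((ns, n_records * spr))
    padded[:, : rec.n_samples] = rec.samples
    scale = (phys_max - (-phys_max)) / (dig_max - dig_min)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig)
        for r in range(n_records):
            for ch in range(ns):
                chunk = padded[ch, r * spr : (r + 1) * spr]
                dig = np.round((chunk - (-phys_max[ch])) / scale[ch]) + dig_min
                dig = np.clip(dig, dig_min, dig_max).astype("<i2")
                fh.write(dig.tobytes())


def edf_quantization_step(rec: EEGRecording) -> np.ndarray:
    """Per-channel physical value of one 16-bit digital step for this writer."""
    phys_max = np.ceil(np.maximum(np.max(np.abs(rec.samples), axis=1), 1.0))
    return 2.0 * phys_max / 65535.0


# ---------------------------------------------------------------------------
# Annotation I/O
# ---------------------------------------------------------------------------

def read_annotations(path: str | Path) -> AnnotationTrack:
    """Read seizure intervals from CSV (onset,offset header) or JSON."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"annotation file not found: {path}")
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        events = [(float(e["onset"]), float(e["offset"])) for e in payload]
    else:
        frame = pd.read_csv(path, float_precision="round_trip")
        missing = {"onset", "offset"} - set(frame.columns)
        if missing:
            raise ValidationError(f"annotation CSV missing columns: {sorted(missing)}")
        events = list(zip(frame["onset"].astype(float), frame["offset"].astype(float)))
    return AnnotationTrack(tuple(events))


def write_annotations(track: AnnotationTrack, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = [{"onset": on, "offset": off} for on, off in track]
        path.write_text(json.dumps(payload, indent=2) + "\n")
    else:
        frame = pd.DataFrame(track.events, columns=["onset", "offset"])
        # %.17g keeps the round trip exact for float64 times
        frame.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Segmentation and labeling
# ---------------------------------------------------------------------------

def segment_recording(rec: EEGRecording) -> dict[str, list[LabeledSegment]]:
    """Cut each channel into consecutive 2-s segments starting at t = 0.

    The trailing partial window, if any, is dropped rather than padded.
    """
    if rec.duration < SEGMENT_SECONDS:
        raise ValidationError(
            f"recording of {rec.duration:.3f} s is shorter than one {SEGMENT_SECONDS:g}-s segment"
        )
    samples_per_segment = int(SEGMENT_SECONDS * rec.sampling_rate)
    n_segments = rec.n_samples // samples_per_segment
    out: dict[str, list[LabeledSegment]] = {}
    for ch_idx, name in enumerate(rec.channel_names):
        row = rec.samples[ch_idx]
        out[name] = [
            LabeledSegment(
                channel=name,
                index=i,
                samples=row[i * samples_per_segment : (i + 1) * samples_per_segment],
            )
            for i in range(n_segments)
        ]
    return out


def label_segments(segments, track: AnnotationTrack):
    """Apply the strict >1-s overlap rule to segments.

    A segment ``[t_start, t_start + 2)`` is ICTAL when its total intersection
    with the union of annotated intervals strictly exceeds 1.0 s, else
    BASELINE (annotations are recording-wide, so labels do not depend on the
    channel).  Accepts either a flat list of segments or the per-channel dict
    from :func:`segment_recording`; returns the same shape.
    """
    if isinstance(segments, Mapping):
        return {ch: label_segments(segs, track) for ch, segs in segments.items()}
    out = []
    for seg in segments:
        overlap = track.overlap(seg.t_start, seg.t_end)
        label = SegmentLabel.ICTAL if overlap > 1.0 else SegmentLabel.BASELINE
        out.append(replace(seg, label=label))
    return out
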