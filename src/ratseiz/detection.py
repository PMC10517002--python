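"""Seizure calling from per-segment labels, and event-overlap matching.

Within one channel, a run of two or more consecutive ICTAL segments becomes a
candidate seizure interval, while an isolated ICTAL segment is scored as
interictal activity.  Candidate intervals that overlap or abut across
channels merge into a single event whose channel set is the union, so a
generalized discharge seen on every electrode counts once while a focal
seizure confined to one channel is still captured.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .errors import ValidationError
from .io import SEGMENT_SECONDS, AnnotationTrack, SegmentLabel

__all__ = ["SeizureEvent", "InterictalMark", "MatchResult", "call_seizures", "match_events"]


@dataclass(frozen=True)
class SeizureEvent:
    """Detected seizure: half-open [start, end) in seconds, with source channels."""

    start: float
    end: float
    channels: frozenset[str] = frozenset()
    source: str = "dcnn"

    def __post_init__(self) -> None:
        if not (self.start < self.end):
            raise ValidationError("event start must precede end")

    @property
    def duration(self) -> float:
        return self.end - self.start

    def overlaps(self, other: "SeizureEvent | tuple[float, float]") -> bool:
        if isinstance(other, tuple):
            o_start, o_end = other
        else:
            o_start, o_end = other.start, other.end
        return min(self.end, o_end) - max(self.start, o_start) > 0


@dataclass(frozen=True)
class InterictalMark:
    """Isolated single ICTAL-classified segment, scored as interictal activity."""

    channel: str
    t_start: float
    t_end: float


@dataclass
class MatchResult:
    """Detections partitioned against a reference track.

    ``true_positives`` holds one (detection, reference interval) pair per
    detection that overlaps any reference seizure; several detections inside
    one reference all pair with it (they overlap a true seizure, so none is a
    false positive).  ``matched_references`` are the reference intervals hit
    by at least one detection; sensitivity is their count over the reference
    count.
    """

    true_positives: list[tuple[SeizureEvent, tuple[float, float]]] = field(default_factory=list)
    false_positives: list[SeizureEvent] = field(default_factory=list)
    false_negatives: list[tuple[float, float]] = field(default_factory=list)

    @property
    def matched_references(self) -> set[tuple[float, float]]:
        return {ref for _, ref in self.true_positives}

    @property
    def n_true_positive_events(self) -> int:
        """Number of reference seizures hit by at least one detection."""
        return len(self.matched_references)

    @property
    def n_false_positives(self) -> int:
        return len(self.false_positives)

    @property
    def n_false_negatives(self) -> int:
        return len(self.false_negatives)


def _is_ictal(label) -> bool:
    if isinstance(label, SegmentLabel):
        return label is SegmentLabel.ICTAL
    return str(label).upper() == "ICTAL"


def call_seizures(
    per_channel_labels: Mapping[str, Sequence],
    segment_duration: float = SEGMENT_SECONDS,
    min_event_duration: float | None = None,
    source: str = "dcnn",
) -> tuple[list[SeizureEvent], list[InterictalMark]]:
    """Convert per-channel segment labels into merged seizure events.

    Labels may be :class:`SegmentLabel` values or "ICTAL"/"BASELINE" strings
    on a common grid anchored at t = 0.  Runs of >= 2 consecutive ICTAL
    segments in a channel become candidate intervals; isolated ICTAL segments
    become interictal marks.  Candidates that overlap or share a boundary
    across channels merge into one event.  ``min_event_duration`` optionally
    discards merged events shorter than that many seconds (used by the
    line-length comparator's 4-s floor; with 2-s segments the >=2-run rule
    already guarantees 4 s).
    """
    lengths = {len(labels) for labels in per_channel_labels.values()}
    if len(lengths) > 1:
        raise ValidationError(f"label sequences differ in length: {sorted(lengths)}")

    candidates: list[tuple[float, float, str]] = []
    interictal: list[InterictalMark] = []
    for channel, labels in per_channel_labels.items():
        i = 0
        n = len(labels)
        while i < n:
            if _is_ictal(labels[i]):
                j = i
                while j < n and _is_ictal(labels[j]):
                    j += 1
                start = i * segment_duration
                end = j * segment_duration
                if j - i >= 2:
                    candidates.append((start, end, channel))
                else:
                    interictal.append(InterictalMark(channel, start, end))
                i = j
            else:
                i += 1

    # merge candidate intervals that overlap or abut, across channels
    candidates.sort(key=lambda c: (c[0], c[1]))
    events: list[SeizureEvent] = []
    cur: list | None = None
    for start, end, channel in candidates:
        if cur is not None and start <= cur[1]:
            cur[1] = max(cur[1], end)
            cur[2].add(channel)
        else:
            if cur is not None:
                events.append(SeizureEvent(cur[0], cur[1], frozenset(cur[2]), source))
            cur = [start, end, {channel}]
    if cur is not None:
        events.append(SeizureEvent(cur[0], cur[1], frozenset(cur[2]), source))

    if min_event_duration is not None:
        events = [e for e in events if e.duration >= min_event_duration]
    # a single ICTAL segment coinciding with another channel's event is part
    # of that seizure, not interictal activity
    interictal = [
        m
        for m in interictal
        if not any(e.start < m.t_end and m.t_start < e.end for e in events)
    ]
    return events, interictal


def match_events(
    detections: Sequence[SeizureEvent],
    reference: AnnotationTrack,
) -> MatchResult:
    """Partition detections into TP/FP and references into matched/FN.

    A detection is a true positive iff it shares positive duration with any
    reference seizure.  Pairing is greedy in chronological order: each
    detection pairs with its earliest overlapping unmatched reference, or —
    when every overlapping reference is already matched — with the earliest
    overlapping one (multiple detections inside a true seizure are not
    penalized as false positives).
    """
    result = MatchResult()
    matched: set[tuple[float, float]] = set()
    dets = sorted(detections, key=lambda e: (e.start, e.end))
    for det in dets:
        overlapping = [ref for ref in reference if det.overlaps(ref)]
        if not overlapping:
            result.false_positives.append(det)
            continue
        unmatched = [ref for ref in overlapping if ref not in matched]
        ref = unmatched[0] if unmatched else overlapping[0]
        matched.add(ref)
        result.true_positives.append((det, ref))
    result.false_negatives = [ref for ref in reference if ref not in matched]
    return result
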