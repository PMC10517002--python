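"""Seizure calling from label grids and event-overlap matching."""

import numpy as np
import pytest

from ratseiz import (
    AnnotationTrack,
    SeizureEvent,
    ValidationError,
    call_seizures,
    match_events,
)

B, I = "BASELINE", "ICTAL"


class TestCallSeizures:
    def test_single_run_becomes_event(self):
        events, marks = call_seizures({"ch": [B, I, I, B]})
        assert len(events) == 1 and not marks
        assert (events[0].start, events[0].end) == (2.0, 6.0)
        assert events[0].channels == {"ch"}

    def test_isolated_ictals_are_interictal_marks(self):
        events, marks = call_seizures({"ch": [B, I, B, I, B]})
        assert events == []
        assert [(m.t_start, m.t_end) for m in marks] == [(2.0, 4.0), (6.0, 8.0)]

    def test_cross_channel_overlap_merges(self):
        events, _ = call_seizures(
            {
                "ch1": [B, B, B, I, I, B, B],
                "ch2": [B, B, B, B, I, I, B],
            }
        )
        assert len(events) == 1
        ev = events[0]
        assert (ev.start, ev.end) == (6.0, 12.0)
        assert ev.channels == {"ch1", "ch2"}

    def test_abutting_runs_merge(self):
        events, _ = call_seizures({"a": [I, I, B, B], "b": [B, B, I, I]})
        assert len(events) == 1
        assert (events[0].start, events[0].end) == (0.0, 8.0)

    def test_no_event_shorter_than_four_seconds(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            grid = {
                f"c{k}": [I if rng.random() < 0.4 else B for _ in range(40)]
                for k in range(4)
            }
            events, marks = call_seizures(grid)
            assert all(e.duration >= 4.0 for e in events)
            for m in marks:
                assert not any(e.start <= m.t_start < e.end for e in events)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValidationError):
            call_seizures({"a": [B, I], "b": [B]})


def brute_force_call(per_channel_labels):
    """Enumerate every consecutive ICTAL pair; union covered segments."""
    n = len(next(iter(per_channel_labels.values())))
    covered_any = np.zeros(n, dtype=bool)
    covered_by = {}
    marks = set()
    for ch, labels in per_channel_labels.items():
        ictal = np.array([l == I for l in labels])
        cov = np.zeros(n, dtype=bool)
        for s in range(n - 1):
            if ictal[s] and ictal[s + 1]:
                cov[s] = cov[s + 1] = True
        covered_by[ch] = cov
        covered_any |= cov
        for s in range(n):
            if ictal[s] and not (s > 0 and ictal[s - 1]) and not (s < n - 1 and ictal[s + 1]):
                marks.add((ch, 2.0 * s))
    events = []
    s = 0
    while s < n:
        if covered_any[s]:
            e = s
            while e < n and covered_any[e]:
                e += 1
            chans = frozenset(
                ch for ch, cov in covered_by.items() if cov[s:e].any()
            )
            events.append((2.0 * s, 2.0 * e, chans))
            s = e
        else:
            s += 1
    # marks swallowed by an event on another channel belong to that seizure
    marks = {
        (ch, t) for ch, t in marks
        if not any(start <= t < end for start, end, _ in events)
    }
    return events, marks


def test_calling_matches_consecutive_pair_scanner_on_random_grids():
    """1000 seeded random 4x100 label grids against the brute-force scanner."""
    rng = np.random.default_rng(77)
    for _ in range(1000):
        p = rng.uniform(0.05, 0.5)
        grid = {
            f"c{k}": [I if rng.random() < p else B for _ in range(100)]
            for k in range(4)
        }
        events, marks = call_seizures(grid)
        got = [(e.start, e.end, e.channels) for e in events]
        got_marks = {(m.channel, m.t_start) for m in marks}
        exp_events, exp_marks = brute_force_call(grid)
        assert got == exp_events
        assert got_marks == exp_marks


class TestMatchEvents:
    def test_overlapping_detection_is_tp(self):
        res = match_events(
            [SeizureEvent(10.0, 14.0)], AnnotationTrack(((12.0, 20.0),))
        )
        assert res.n_true_positive_events == 1
        assert res.n_false_positives == 0 and res.n_false_negatives == 0

    def test_detection_without_reference_is_fp(self):
        res = match_events([SeizureEvent(0.0, 4.0)], AnnotationTrack())
        assert res.n_false_positives == 1

    def test_unmatched_reference_is_fn(self):
        res = match_events([], AnnotationTrack(((50.0, 60.0),)))
        assert res.n_false_negatives == 1

    def test_touching_intervals_do_not_overlap(self):
        # half-open intervals: [6,10) and [10,14) share no duration
        res = match_events([SeizureEvent(6.0, 10.0)], AnnotationTrack(((10.0, 14.0),)))
        assert res.n_false_positives == 1 and res.n_false_negatives == 1

    def test_multiple_detections_in_one_reference_add_no_fp(self):
        res = match_events(
            [SeizureEvent(10.0, 14.0), SeizureEvent(16.0, 20.0)],
            AnnotationTrack(((9.0, 21.0),)),
        )
        assert res.n_true_positive_events == 1
        assert res.n_false_positives == 0
        assert len(res.true_positives) == 2  # every detection accounted for

    def test_partition_invariants_on_random_cases(self):
        rng = np.random.default_rng(13)
        for _ in range(200):
            dets = []
            t = 0.0
            for _ in range(rng.integers(0, 8)):
                t += rng.uniform(0, 30)
                d = rng.uniform(4, 20)
                dets.append(SeizureEvent(t, t + d))
                t += d
            refs = []
            t = 0.0
            for _ in range(rng.integers(0, 6)):
                t += rng.uniform(0, 40)
                d = rng.uniform(4, 30)
                refs.append((t, t + d))
                t += d
            track = AnnotationTrack(tuple(refs))
            res = match_events(dets, track)
            assert len(res.true_positives) + len(res.false_positives) == len(dets)
            assert res.n_true_positive_events + res.n_false_negatives == len(track)
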