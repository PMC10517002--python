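"""Accuracy metrics against visual-style reference annotations, and the feature GLM.

Segment-level metrics pool all channels: overall accuracy over every 2-s
segment, and ictal-segment accuracy (the fraction of segments inside
reference seizures that the classifier called ICTAL).  Event-level metrics
come from overlap matching: seizure sensitivity (matched references /
references), false positives per recorded hour, and the false-positive
fraction of all detections.  The feature-selection GLM is a binary logistic
regression of segment label on kurtosis, spectral entropy and line length,
reported JMP-style with Wald p-values and LogWorth (-log10 p).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .detection import MatchResult, SeizureEvent, match_events
from .errors import ValidationError
from .io import SEGMENT_SECONDS, AnnotationTrack, SegmentLabel

__all__ = [
    "EvaluationReport",
    "GLMFit",
    "evaluate",
    "evaluate_events",
    "fit_segment_glm",
    "compare_detectors",
]


@dataclass
class EvaluationReport:
    overall_accuracy: float
    ictal_segment_accuracy: float
    seizure_sensitivity: float
    fp_per_hour: float
    fp_fraction: float
    n_segments: int = 0
    n_reference_events: int = 0
    n_detections: int = 0
    n_true_positive_events: int = 0
    n_false_positives: int = 0
    n_false_negatives: int = 0
    duration_hours: float = 0.0
    reference_signature: tuple = field(default=())

    def to_dict(self) -> dict:
        return {
            "overall_accuracy": self.overall_accuracy,
            "ictal_segment_accuracy": self.ictal_segment_accuracy,
            "seizure_sensitivity": self.seizure_sensitivity,
            "fp_per_hour": self.fp_per_hour,
            "fp_fraction": self.fp_fraction,
            "n_segments": self.n_segments,
            "n_reference_events": self.n_reference_events,
            "n_detections": self.n_detections,
            "n_true_positive_events": self.n_true_positive_events,
            "n_false_positives": self.n_false_positives,
            "n_false_negatives": self.n_false_negatives,
            "duration_hours": self.duration_hours,
        }


def _reference_signature(track: AnnotationTrack, duration: float) -> tuple:
    return (len(track), round(track.total_duration(), 6), round(duration, 6))


def _grid_labels(track: AnnotationTrack, n_segments: int) -> np.ndarray:
    """Ground-truth ICTAL mask on the 2-s grid (strict >1-s overlap rule)."""
    mask = np.zeros(n_segments, dtype=bool)
    for i in range(n_segments):
        t0 = i * SEGMENT_SECONDS
        mask[i] = track.overlap(t0, t0 + SEGMENT_SECONDS) > 1.0
    return mask


def _as_ictal_mask(labels: Sequence) -> np.ndarray:
    out = np.zeros(len(labels), dtype=bool)
    for i, lab in enumerate(labels):
        name = lab.value if isinstance(lab, SegmentLabel) else str(lab).upper()
        out[i] = name == "ICTAL"
    return out


def evaluate(
    predicted_labels: Mapping[str, Sequence],
    detections: Sequence[SeizureEvent],
    reference_track: AnnotationTrack,
    duration: float,
) -> EvaluationReport:
    """Score per-channel predicted segment labels and called events.

    Ground truth on the segment grid is derived from the reference track with
    the same strict >1-s rule used for training labels; segment metrics pool
    all channels (annotations are recording-wide, so every channel shares the
    same truth sequence).
    """
    if duration <= 0:
        raise ValidationError("duration must be positive")
    n_grid = int(duration // SEGMENT_SECONDS)
    for ch, labels in predicted_labels.items():
        if len(labels) != n_grid:
            raise ValidationError(
                f"channel {ch!r} has {len(labels)} labels but the grid has {n_grid} segments"
            )
    truth = _grid_labels(reference_track, n_grid)

    n_total = 0
    n_correct = 0
    n_ictal_truth = 0
    n_ictal_hit = 0
    for labels in predicted_labels.values():
        pred = _as_ictal_mask(labels)
        n_total += n_grid
        n_correct += int((pred == truth).sum())
        n_ictal_truth += int(truth.sum())
        n_ictal_hit += int((pred & truth).sum())

    match = match_events(detections, reference_track)
    return _build_report(
        n_correct / n_total if n_total else math.nan,
        n_ictal_hit / n_ictal_truth if n_ictal_truth else math.nan,
        match,
        reference_track,
        duration,
        n_total,
    )


def evaluate_events(
    detections: Sequence[SeizureEvent],
    reference_track: AnnotationTrack,
    duration: float,
) -> EvaluationReport:
    """Score a detector from its events alone.

    Segment-level predictions are reconstructed from the detected intervals
    with the same >1-s overlap rule, on a single recording-wide track (used
    for the line-length comparator, which labels windows rather than 2-s
    segments).
    """
    det_track = AnnotationTrack(tuple((e.start, e.end) for e in detections))
    n_grid = int(duration // SEGMENT_SECONDS)
    pred = ["ICTAL" if m else "BASELINE" for m in _grid_labels(det_track, n_grid)]
    return evaluate({"all": pred}, detections, reference_track, duration)


def _build_report(overall, ictal_acc, match: MatchResult, track, duration, n_segments):
    n_ref = len(track)
    n_det = len(match.true_positives) + len(match.false_positives)
    hours = duration / 3600.0
    return EvaluationReport(
        overall_accuracy=overall,
        ictal_segment_accuracy=ictal_acc,
        seizure_sensitivity=(match.n_true_positive_events / n_ref) if n_ref else math.nan,
        fp_per_hour=match.n_false_positives / hours,
        fp_fraction=(match.n_false_positives / n_det) if n_det else 0.0,
        n_segments=n_segments,
        n_reference_events=n_ref,
        n_detections=n_det,
        n_true_positive_events=match.n_true_positive_events,
        n_false_positives=match.n_false_positives,
        n_false_negatives=match.n_false_negatives,
        duration_hours=hours,
        reference_signature=_reference_signature(track, duration),
    )


# ---------------------------------------------------------------------------
# Feature-selection GLM
# ---------------------------------------------------------------------------

FEATURE_COLUMNS = ("kurtosis", "entropy", "line_length")


@dataclass
class GLMFit:
    """Nominal-logistic fit of ICTAL(1)/BASELINE(0) on the three features."""

    intercept: float
    coef_kurtosis: float
    coef_entropy: float
    coef_linelength: float
    pvalues: dict
    logworth: dict
    separation: bool = False
    converged: bool = True
    dropped: tuple = ()

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        coefs = {
            "intercept": self.intercept,
            "kurtosis": self.coef_kurtosis,
            "entropy": self.coef_entropy,
            "line_length": self.coef_linelength,
        }
        for name, beta in coefs.items():
            rows.append(
                {
                    "term": name,
                    "beta": beta,
                    "p_value": self.pvalues.get(name, math.nan),
                    "logworth": self.logworth.get(name, math.nan),
                }
            )
        return pd.DataFrame(rows)


def fit_segment_glm(feature_table: pd.DataFrame, labels=None) -> GLMFit:
    """Binary logistic regression of segment label on the three features.

    ``feature_table`` needs kurtosis, entropy and line_length columns; labels
    come either from a ``label`` column or the ``labels`` argument.  Constant
    features are dropped with a warning (their coefficient is reported as
    NaN); quasi-complete separation sets the ``separation`` flag instead of
    failing.
    """
    table = feature_table.copy()
    if "spectral_entropy" in table.columns and "entropy" not in table.columns:
        table = table.rename(columns={"spectral_entropy": "entropy"})
    missing = [c for c in FEATURE_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"feature table missing columns: {missing}")
    if labels is None:
        if "label" not in table.columns:
            raise ValidationError("labels must be given or present as a 'label' column")
        labels = table["label"]
    y = _as_ictal_mask(list(labels)).astype(float)
    if len(y) != len(table):
        raise ValidationError("labels and feature table differ in length")
    if y.min() == y.max():
        raise ValidationError("GLM needs both ICTAL and BASELINE segments")
    counts = pd.Series(y).value_counts()
    if counts.min() < 2:
        raise ValidationError("GLM needs at least 2 segments per class")

    X = table[list(FEATURE_COLUMNS)].to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValidationError("features must be finite")
    dropped = tuple(
        FEATURE_COLUMNS[j] for j in range(X.shape[1]) if np.ptp(X[:, j]) == 0
    )
    if dropped:
        warnings.warn(f"constant features dropped from GLM: {dropped}", stacklevel=2)
    keep = [j for j in range(X.shape[1]) if FEATURE_COLUMNS[j] not in dropped]
    design = sm.add_constant(X[:, keep], has_constant="add")

    separation = False
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, design).fit(disp=0, maxiter=200)
        except Exception:  # newton can fail outright under separation
            separation = True
            res = sm.Logit(y, design).fit(disp=0, maxiter=500, method="lbfgs")
    converged = bool(res.mle_retvals.get("converged", True))
    if not converged or np.max(np.abs(res.params)) > 1e3:
        separation = separation or np.max(np.abs(res.params)) > 1e3

    names = ["intercept"] + [FEATURE_COLUMNS[j] for j in keep]
    params = dict(zip(names, res.params))
    pvals = dict(zip(names, res.pvalues))
    logworth = {
        k: (-math.log10(p) if p > 0 else math.inf) for k, p in pvals.items()
    }
    return GLMFit(
        intercept=params.get("intercept", math.nan),
        coef_kurtosis=params.get("kurtosis", math.nan),
        coef_entropy=params.get("entropy", math.nan),
        coef_linelength=params.get("line_length", math.nan),
        pvalues=pvals,
        logworth=logworth,
        separation=separation,
        converged=converged,
        dropped=dropped,
    )


# ---------------------------------------------------------------------------
# Detector comparison
# ---------------------------------------------------------------------------

def compare_detectors(
    report_a: EvaluationReport,
    report_b: EvaluationReport,
    names: tuple[str, str] = ("dcnn", "linelength"),
) -> pd.DataFrame:
    """Side-by-side sensitivity / FP metrics with differences (A minus B)."""
    if report_a.reference_signature != report_b.reference_signature:
        raise ValidationError(
            "reports were computed against different references and cannot be compared"
        )
    metrics = ["seizure_sensitivity", "fp_fraction", "fp_per_hour", "ictal_segment_accuracy", "overall_accuracy"]
    rows = []
    for m in metrics:
        a = getattr(report_a, m)
        b = getattr(report_b, m)
        rows.append({"metric": m, names[0]: a, names[1]: b, "difference": a - b})
    return pd.DataFrame(rows)
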