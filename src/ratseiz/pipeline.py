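"""End-to-end glue: featurize a recording, train, detect, evaluate.

These helpers stream segment images one at a time so multi-hour recordings
never materialize thousands of 224x224x3 arrays at once; the classifier's
preprocessing compacts each image as it is produced.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .classifier import TrainedClassifier, TrainingConfig, classify_segments, train_classifier
from .detection import SeizureEvent, call_seizures
from .features import FeatureVector, compute_features, compute_scalogram
from .io import AnnotationTrack, EEGRecording, SegmentLabel, label_segments, segment_recording
from .multiplex import MultiplexWeights, apply_multiplex, multiplex_factor

__all__ = [
    "SegmentImages",
    "ExperimentResult",
    "iter_segment_images",
    "featurize",
    "train_from_recording",
    "detect_with_classifier",
    "run_detection_experiment",
]


@dataclass
class SegmentImages:
    """One segment's images (by mode) plus its scalar features and label."""

    channel: str
    index: int
    label: SegmentLabel
    features: FeatureVector
    images: dict[str, np.ndarray]


def iter_segment_images(
    recording: EEGRecording,
    track: AnnotationTrack | None = None,
    weights: MultiplexWeights | None = None,
    modes: Sequence[str] = ("multiplexed",),
    stage: str = "post-colormap",
    f_min: float = 1.0,
    f_max: float = 24.0,
    voices_per_octave: int = 12,
) -> Iterator[SegmentImages]:
    """Yield per-segment images channel by channel, in grid order.

    ``modes`` selects which images to build from the one CWT per segment:
    "scalogram" (colormapped scalogram alone) and/or "multiplexed"
    (scalogram scaled by the kurtosis / inverse-entropy factor).  With
    ``stage="pre-colormap"`` the factor is applied to the normalized CWT
    magnitude before colormapping instead of to the RGB image.
    """
    if weights is None:
        weights = MultiplexWeights()
    segments = segment_recording(recording)
    if track is not None:
        segments = label_segments(segments, track)
    for channel in recording.channel_names:
        for seg in segments[channel]:
            fv = compute_features(seg.samples)
            images: dict[str, np.ndarray] = {}
            scal = None
            if "scalogram" in modes or stage == "post-colormap":
                scal = compute_scalogram(
                    seg.samples, recording.sampling_rate, f_min, f_max, voices_per_octave
                )
            if "scalogram" in modes:
                images["scalogram"] = scal.pixels
            if "multiplexed" in modes:
                if stage == "pre-colormap":
                    gain = multiplex_factor(fv, weights)
                    images["multiplexed"] = compute_scalogram(
                        seg.samples,
                        recording.sampling_rate,
                        f_min,
                        f_max,
                        voices_per_octave,
                        intensity_gain=gain,
                    ).pixels
                else:
                    images["multiplexed"] = apply_multiplex(scal, fv, weights).pixels
            yield SegmentImages(
                channel=channel, index=seg.index, label=seg.label, features=fv, images=images
            )


def featurize(
    recording: EEGRecording,
    track: AnnotationTrack | None = None,
    recording_id: str = "recording",
) -> pd.DataFrame:
    """Scalar feature table (no images): one row per channel x segment."""
    segments = segment_recording(recording)
    if track is not None:
        segments = label_segments(segments, track)
    from .features import feature_table

    return feature_table(segments, recording_id=recording_id)


def train_from_recording(
    recording: EEGRecording,
    track: AnnotationTrack,
    config: TrainingConfig | None = None,
    weights: MultiplexWeights | None = None,
    mode: str = "multiplexed",
) -> TrainedClassifier:
    """Label a training recording, build its images, and fit a classifier."""
    stream = iter_segment_images(recording, track, weights, modes=(mode,))
    labels: list[SegmentLabel] = []

    def images():
        for item in stream:
            labels.append(item.label)
            yield item.images[mode]

    # train_classifier consumes the generator fully before reading labels
    return train_classifier(images(), _Lazy(labels), config)


class _Lazy(Sequence):
    """Labels list filled while the image generator is consumed."""

    def __init__(self, backing: list):
        self._backing = backing

    def __len__(self):
        return len(self._backing)

    def __getitem__(self, i):
        return self._backing[i]

    def __iter__(self):
        return iter(self._backing)


def detect_with_classifier(
    recording: EEGRecording,
    classifier: TrainedClassifier,
    weights: MultiplexWeights | None = None,
    mode: str = "multiplexed",
) -> tuple[dict[str, list[SegmentLabel]], list[SeizureEvent], list]:
    """Classify every segment and call seizures with the >=2-consecutive rule.

    Returns (per-channel predicted labels, merged seizure events, interictal
    marks).
    """
    stream = iter_segment_images(recording, weights=weights, modes=(mode,))
    order: list[str] = []

    def images():
        for item in stream:
            order.append(item.channel)
            yield item.images[mode]

    flat = classify_segments(classifier, images())
    by_channel: dict[str, list[SegmentLabel]] = {ch: [] for ch in recording.channel_names}
    for ch, lab in zip(order, flat):
        by_channel[ch].append(lab)
    events, interictal = call_seizures(by_channel)
    return by_channel, events, interictal


# ---------------------------------------------------------------------------
# Train-on-one-record / evaluate-on-another experiment
# ---------------------------------------------------------------------------


@dataclass
class ExperimentResult:
    classifier: TrainedClassifier
    labels_by_channel: dict
    events: list
    report: object  # EvaluationReport


def _block_mean(image: np.ndarray, size: int) -> np.ndarray:
    H, W, C = image.shape
    if H % size == 0 and W % size == 0:
        return (
            image.reshape(size, H // size, size, W // size, C)
            .mean(axis=(1, 3))
            .astype(np.float32)
        )
    from skimage.transform import resize

    return resize(image, (size, size), order=1, anti_aliasing=False).astype(np.float32)


def run_detection_experiment(
    train_recording: EEGRecording,
    train_track: AnnotationTrack,
    eval_recording: EEGRecording,
    eval_track: AnnotationTrack,
    config: TrainingConfig | None = None,
    weights: MultiplexWeights | None = None,
    modes: Sequence[str] = ("multiplexed", "scalogram"),
    image_size: int = 32,
) -> dict[str, ExperimentResult]:
    """Train on one annotated recording, detect and score on another.

    One featurization pass builds the images for every requested mode (the
    CWT per segment is shared), block-averaged down to ``image_size`` so an
    hour-long evaluation record fits in memory; 224 is a multiple of 32, so
    this pooling commutes with the tiny-cnn's own input reduction.  Returns
    one :class:`ExperimentResult` per mode.
    """
    from .evaluation import evaluate

    train_images: dict[str, list[np.ndarray]] = {m: [] for m in modes}
    labels: list[SegmentLabel] = []
    for item in iter_segment_images(train_recording, train_track, weights, modes):
        labels.append(item.label)
        for m in modes:
            train_images[m].append(_block_mean(item.images[m], image_size))

    eval_images: dict[str, list[np.ndarray]] = {m: [] for m in modes}
    order: list[str] = []
    for item in iter_segment_images(eval_recording, weights=weights, modes=modes):
        order.append(item.channel)
        for m in modes:
            eval_images[m].append(_block_mean(item.images[m], image_size))

    results: dict[str, ExperimentResult] = {}
    for m in modes:
        clf = train_classifier(train_images[m], labels, config)
        flat = classify_segments(clf, eval_images[m])
        by_channel: dict[str, list[SegmentLabel]] = {
            ch: [] for ch in eval_recording.channel_names
        }
        for ch, lab in zip(order, flat):
            by_channel[ch].append(lab)
        events, _ = call_seizures(by_channel)
        report = evaluate(by_channel, events, eval_track, eval_recording.duration)
        results[m] = ExperimentResult(
            classifier=clf, labels_by_channel=by_channel, events=events, report=report
        )
    return results
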