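"""Per-segment features: CWT scalogram image, kurtosis, spectral entropy, line length.

The scalogram is the magnitude of an analytic-Morlet continuous wavelet
transform over 1-24 Hz with 12 voices per octave, min-max rescaled per image,
resampled to 224x224 and mapped through a 128-level jet colormap to RGB —
the image fed to the classifier.  Kurtosis (fourth standardized moment,
Gaussian = 3) indexes waveform sharpness; spectral entropy (Shannon entropy
of the normalized half-spectrum power, scaled to a 0-1 range) drops for the
rhythmic narrowband activity typical of spike-wave seizures; line length is
the summed absolute first difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from matplotlib import colormaps
from scipy import stats
from skimage.transform import resize

from .errors import DegenerateSignalError, ValidationError

IMAGE_SIZE = 224
COLORMAP_LEVELS = 128
DEFAULT_WAVELET = "cmor1.5-1.0"  # analytic (complex) Morlet

__all__ = [
    "FeatureVector",
    "ScalogramImage",
    "cwt_magnitude",
    "compute_scalogram",
    "compute_kurtosis",
    "compute_spectral_entropy",
    "compute_line_length",
    "compute_features",
    "feature_table",
]


@dataclass(frozen=True)
class FeatureVector:
    """The three scalar per-segment predictors."""

    kurtosis: float
    spectral_entropy: float
    line_length: float


@dataclass
class ScalogramImage:
    """224x224x3 RGB intensity array with the per-row centre frequency."""

    pixels: np.ndarray
    freq_axis: np.ndarray  # Hz, descending, one per row

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.shape != (IMAGE_SIZE, IMAGE_SIZE, 3):
            raise ValidationError(
                f"scalogram image must be {IMAGE_SIZE}x{IMAGE_SIZE}x3, got {self.pixels.shape}"
            )
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValidationError("scalogram pixel intensities must lie in [0, 1]")


def _voice_frequencies(f_min: float, f_max: float, voices_per_octave: int) -> np.ndarray:
    """Descending geometric frequency grid covering [f_min, f_max]."""
    n_octaves = np.log2(f_max / f_min)
    n = int(np.ceil(n_octaves * voices_per_octave)) + 1
    return np.geomspace(f_max, f_min, n)


def cwt_magnitude(
    segment: np.ndarray,
    sampling_rate: float,
    f_min: float = 1.0,
    f_max: float = 24.0,
    voices_per_octave: int = 12,
    wavelet: str = DEFAULT_WAVELET,
) -> tuple[np.ndarray, np.ndarray]:
    """Raw CWT magnitude (freqs x time, frequency descending) and its frequency axis."""
    segment = np.asarray(segment, dtype=float)
    if segment.size == 0:
        raise ValidationError("segment is empty")
    if not (0 < f_min < f_max):
        raise ValidationError("need 0 < f_min < f_max")
    if f_max >= sampling_rate / 2:
        raise ValidationError(
            f"f_max={f_max} Hz reaches the Nyquist frequency ({sampling_rate / 2} Hz)"
        )
    freqs = _voice_frequencies(f_min, f_max, voices_per_octave)
    wav = pywt.ContinuousWavelet(wavelet)
    scales = pywt.frequency2scale(wav, freqs / sampling_rate)
    coef, actual_freqs = pywt.cwt(
        segment, scales, wav, sampling_period=1.0 / sampling_rate, method="fft"
    )
    return np.abs(coef), np.asarray(actual_freqs)


def compute_scalogram(
    segment: np.ndarray,
    sampling_rate: float,
    f_min: float = 1.0,
    f_max: float = 24.0,
    voices_per_octave: int = 12,
    wavelet: str = DEFAULT_WAVELET,
    intensity_gain: float = 1.0,
) -> ScalogramImage:
    """Colormapped 224x224x3 scalogram of one segment.

    ``intensity_gain`` multiplies the min-max-normalized magnitude before the
    colormap (with clipping at 1); it is how pre-colormap multiplexing is
    expressed.  An all-zero segment yields the constant colormap-of-zero
    image.
    """
    mag, freqs = cwt_magnitude(
        segment, sampling_rate, f_min, f_max, voices_per_octave, wavelet
    )
    lo, hi = mag.min(), mag.max()
    if hi > lo:
        norm = (mag - lo) / (hi - lo)
    else:
        norm = np.zeros_like(mag)
    if intensity_gain != 1.0:
        norm = np.clip(norm * intensity_gain, 0.0, 1.0)
    small = resize(norm, (IMAGE_SIZE, IMAGE_SIZE), order=1, anti_aliasing=False)
    small = np.clip(small, 0.0, 1.0)
    cmap = colormaps["jet"].resampled(COLORMAP_LEVELS)
    rgb = cmap(small)[..., :3]
    # interpolate the voice grid onto the 224 image rows (log-frequency axis)
    row_pos = np.linspace(0, len(freqs) - 1, IMAGE_SIZE)
    row_freqs = np.exp(np.interp(row_pos, np.arange(len(freqs)), np.log(freqs)))
    return ScalogramImage(pixels=rgb, freq_axis=row_freqs)


def compute_kurtosis(segment: np.ndarray) -> float:
    """Pearson (non-excess) kurtosis m4/m2^2, no bias correction."""
    segment = np.asarray(segment, dtype=float)
    if segment.size <= 3:
        raise ValidationError("kurtosis needs more than 3 samples")
    if np.ptp(segment) == 0:
        raise DegenerateSignalError("kurtosis is undefined for a constant segment")
    return float(stats.kurtosis(segment, fisher=False, bias=True))


def compute_spectral_entropy(segment: np.ndarray) -> float:
    """Normalized Shannon entropy of the half-spectrum power distribution.

    The PSD is |rfft(x)|^2 of the raw (un-windowed) segment; it is normalized
    to a probability distribution over the n//2 + 1 half-spectrum bins and the
    entropy divided by log of the bin count, so a flat spectrum (unit impulse)
    scores exactly 1 and a single on-grid tone scores 0.
    """
    segment = np.asarray(segment, dtype=float)
    if segment.size == 0:
        raise ValidationError("segment is empty")
    psd = np.abs(np.fft.rfft(segment)) ** 2
    total = psd.sum()
    if total <= 0 or np.ptp(segment) == 0:
        raise DegenerateSignalError("spectral entropy is undefined for a zero-power/constant segment")
    p = psd / total
    nz = p[p > 0]
    h = -np.sum(nz * np.log(nz))
    return float(h / np.log(len(p)))


def compute_line_length(segment: np.ndarray) -> float:
    """Sum of absolute consecutive-sample differences, in microvolts."""
    segment = np.asarray(segment, dtype=float)
    if segment.size < 2:
        raise ValidationError("line length needs at least 2 samples")
    return float(np.sum(np.abs(np.diff(segment))))


def compute_features(segment: np.ndarray) -> FeatureVector:
    """All three scalar features of one segment."""
    return FeatureVector(
        kurtosis=compute_kurtosis(segment),
        spectral_entropy=compute_spectral_entropy(segment),
        line_length=compute_line_length(segment),
    )


def feature_table(segments_by_channel, recording_id: str = "recording"):
    """Per-segment feature table (one row per channel x segment).

    Accepts the labeled per-channel dict from ``segment_recording`` /
    ``label_segments``; returns a DataFrame with columns recording, channel,
    segment_index, kurtosis, entropy, line_length, label.
    """
    import pandas as pd

    rows = []
    for channel, segments in segments_by_channel.items():
        for seg in segments:
            fv = compute_features(seg.samples)
            rows.append(
                {
                    "recording": recording_id,
                    "channel": channel,
                    "segment_index": seg.index,
                    "kurtosis": fv.kurtosis,
                    "entropy": fv.spectral_entropy,
                    "line_length": fv.line_length,
                    "label": seg.label.value,
                }
            )
    return pd.DataFrame(rows)
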