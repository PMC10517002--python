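"""Multiplexing: scale the scalogram image by kurtosis and inverse spectral entropy.

The scalar factor is a weight-normalized convex combination
``(w_k * K + w_e * (1/H)) / (w_k + w_e)``, so pure-kurtosis (1, 0),
pure-inverse-entropy (0, 1), the 5:1 mixes, and the default equal weighting
are all points on one axis.  The factor multiplies the RGB image with
clipping at 1 (a pre-colormap variant is available through
``features.compute_scalogram(intensity_gain=...)``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateSignalError, ValidationError
from .features import FeatureVector, ScalogramImage

__all__ = [
    "MultiplexWeights",
    "MultiplexedImage",
    "multiplex_factor",
    "apply_multiplex",
    "save_image_png",
]


@dataclass(frozen=True)
class MultiplexWeights:
    """Non-negative weights for kurtosis and inverse spectral entropy."""

    w_kurtosis: float = 1.0
    w_entropy: float = 1.0

    def __post_init__(self) -> None:
        if self.w_kurtosis < 0 or self.w_entropy < 0:
            raise ValidationError("multiplex weights must be non-negative")
        if self.w_kurtosis + self.w_entropy <= 0:
            raise ValidationError("at least one multiplex weight must be positive")


@dataclass
class MultiplexedImage:
    """Scalogram image scaled by the feature factor, clipped to [0, 1]."""

    pixels: np.ndarray
    source_features: FeatureVector
    weights: MultiplexWeights


def multiplex_factor(features: FeatureVector, weights: MultiplexWeights) -> float:
    """Convex combination of kurtosis and inverse spectral entropy."""
    if features.spectral_entropy <= 0:
        raise DegenerateSignalError(
            "multiplex factor needs spectral entropy > 0 (inverse entropy diverges)"
        )
    wk, we = weights.w_kurtosis, weights.w_entropy
    return (wk * features.kurtosis + we * (1.0 / features.spectral_entropy)) / (wk + we)


def apply_multiplex(
    scalogram: ScalogramImage,
    features: FeatureVector,
    weights: MultiplexWeights | None = None,
) -> MultiplexedImage:
    """Multiply the scalogram RGB image by the multiplex factor, clip to [0, 1]."""
    if weights is None:
        weights = MultiplexWeights()
    factor = multiplex_factor(features, weights)
    pixels = np.clip(scalogram.pixels * factor, 0.0, 1.0)
    return MultiplexedImage(pixels=pixels, source_features=features, weights=weights)


def save_image_png(image, path) -> None:
    """Write a scalogram or multiplexed image to PNG for visual inspection."""
    import imageio.v3 as iio

    pixels = np.asarray(getattr(image, "pixels", image))
    iio.imwrite(str(path), (np.clip(pixels, 0.0, 1.0) * 255).astype(np.uint8))
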