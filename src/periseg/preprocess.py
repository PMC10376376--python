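"""Grayscale conversion, bright-extreme redistribution and frequency-domain
Gaussian high-pass enhancement.

The enhancement is high-boost sharpening: the centered spectrum of the
image is multiplied by the Gaussian high-pass transfer function

    H(u, v) = 1 - exp(-D(u, v)^2 / (2 * D0^2)),

with D the Euclidean distance from the zero-frequency origin, and the
(real) high-frequency component scaled by a gain k is added back to the
image.  H(0,0) = 0, so flat regions are untouched while edges overshoot,
which is what separates tooth contours from gingiva on a radiograph.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .util import round_half_up

__all__ = [
    "FilterSpec",
    "FormatError",
    "to_grayscale",
    "redistribute_bright",
    "gaussian_highpass",
    "enhance",
    "default_cutoff",
]

# ITU-R 601 luma weights, the standard RGB -> gray reduction.
_LUMA = np.array([0.299, 0.587, 0.114])


class FormatError(ValueError):
    """Input raster has an unsupported dtype or channel layout."""


@dataclass
class FilterSpec:
    """Gaussian high-pass parameters: cutoff ``d0`` (frequency-plane pixels)
    and high-boost gain ``strength`` (k; 0 disables the enhancement)."""
    d0: float
    strength: float = 1.0

    def validate(self) -> None:
        if not (self.d0 > 0):
            raise ValueError("d0 must be > 0")
        if self.strength < 0:
            raise ValueError("strength must be >= 0")


def default_cutoff(shape: tuple[int, int]) -> float:
    """Default D0 scales with the image diagonal (5% of it)."""
    h, w = shape
    return 0.05 * float(np.hypot(h, w))


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Reduce an 8-bit raster to a single luminance channel.

    3-channel input is combined with ITU-R 601 weights and rounded half-up;
    single-channel input passes through unchanged.
    """
    image = np.asarray(image)
    if image.dtype != np.uint8:
        raise FormatError(f"expected uint8 input, got {image.dtype}")
    if image.ndim == 2:
        return image.copy()
    if image.ndim == 3 and image.shape[2] == 3:
        gray = image.astype(np.float64) @ _LUMA
        return round_half_up(gray).astype(np.uint8)
    raise FormatError(f"expected HxW or HxWx3 raster, got shape {image.shape}")


def redistribute_bright(img: np.ndarray, cutoff: int = 170) -> np.ndarray:
    """Compress extremely bright pixels (> cutoff) into (cutoff-30, cutoff].

    Pixels at or below the cutoff are untouched; brighter ones are mapped
    linearly (and monotonically) into the 30-level band just under it, so
    external-lighting extremes cannot distort the histogram windows used by
    the adaptive threshold.
    """
    if not (0 < cutoff < 255):
        raise ValueError("cutoff must be in (0, 255)")
    img = np.asarray(img)
    lut = np.arange(256, dtype=np.float64)
    hi = lut > cutoff
    span = max(1, 255 - (cutoff + 1))   # degenerate when cutoff == 254
    lut[hi] = (cutoff - 29) + np.floor(
        (lut[hi] - (cutoff + 1)) * 29.0 / span + 0.5)
    return lut.astype(np.uint8)[img]


def _transfer(shape: tuple[int, int], d0: float) -> np.ndarray:
    h, w = shape
    fy = np.fft.fftfreq(h) * h
    fx = np.fft.fftfreq(w) * w
    d2 = fy[:, None] ** 2 + fx[None, :] ** 2
    return 1.0 - np.exp(-d2 / (2.0 * d0 * d0))


def gaussian_highpass(img: np.ndarray, spec: FilterSpec) -> np.ndarray:
    """High-frequency component of ``img`` (real-valued, mean ~ 0)."""
    spec.validate()
    x = np.asarray(img, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("image contains non-finite pixels")
    H = _transfer(x.shape, spec.d0)
    return np.real(np.fft.ifft2(np.fft.fft2(x) * H))


def enhance(img: np.ndarray, spec: FilterSpec) -> np.ndarray:
    """High-boost enhancement: clip(round(img + k * highpass(img)), 0, 255)."""
    hp = gaussian_highpass(img, spec)
    out = np.asarray(img, dtype=np.float64) + spec.strength * hp
    return np.clip(np.floor(out + 0.5), 0, 255).astype(np.uint8)
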