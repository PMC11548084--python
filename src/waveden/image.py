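"""Grayscale image container and 8-bit PNG/PGM I/O.

Every stage of the denoising pipeline consumes and produces a
:class:`GrayImage`: a 2-D float array together with a declared value range,
either ``"unit"`` ([0, 1]) or ``"eight_bit"`` ([0, 255]).  Carrying the range
explicitly lets each stage work on the scale its parameters are defined on
(the bilateral filter's colour sigma lives on the 8-bit scale, the quality
metrics on the unit scale) without guessing from pixel statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np

__all__ = ["GrayImage", "VALUE_RANGES", "read_image", "write_image"]

#: Declared scales: name -> peak intensity.
VALUE_RANGES = {"unit": 1.0, "eight_bit": 255.0}

_MIN_SIDE = 8  # smallest side the downstream stages (5-level DWT padding, SSIM windows) support


@dataclass(frozen=True)
class GrayImage:
    """A single-channel image with an explicit intensity scale.

    Parameters
    ----------
    pixels:
        2-D float array of intensities.  Stored as ``float64``; the
        constructor copies and validates.
    value_range:
        Declared scale, ``"unit"`` for [0, 1] or ``"eight_bit"`` for [0, 255].
        Pixel values are expected to lie inside the declared range after any
        clipping operation, but intermediate float images may exceed it
        slightly (e.g. wavelet reconstructions); only NaN/inf are rejected.
    """

    pixels: np.ndarray
    value_range: str = "unit"
    # cached, derived — not part of equality
    height: int = field(init=False, compare=False)
    width: int = field(init=False, compare=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels, dtype=np.float64)
        if arr.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {arr.shape}")
        if arr.shape[0] < _MIN_SIDE or arr.shape[1] < _MIN_SIDE:
            raise ValueError(
                f"image must be at least {_MIN_SIDE}x{_MIN_SIDE}, got {arr.shape}"
            )
        if not np.all(np.isfinite(arr)):
            raise ValueError("pixels must be finite")
        if self.value_range not in VALUE_RANGES:
            raise ValueError(
                f"value_range must be one of {sorted(VALUE_RANGES)}, got {self.value_range!r}"
            )
        object.__setattr__(self, "pixels", arr)
        object.__setattr__(self, "height", arr.shape[0])
        object.__setattr__(self, "width", arr.shape[1])

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)

    @property
    def peak(self) -> float:
        """Maximum representable intensity of the declared range."""
        return VALUE_RANGES[self.value_range]

    def to_unit(self) -> "GrayImage":
        """Return this image on the unit [0, 1] scale."""
        if self.value_range == "unit":
            return self
        return GrayImage(self.pixels / 255.0, "unit")

    def to_eight_bit(self) -> "GrayImage":
        """Return this image on the 8-bit [0, 255] float scale (no quantization)."""
        if self.value_range == "eight_bit":
            return self
        return GrayImage(self.pixels * 255.0, "eight_bit")

    def clipped(self) -> "GrayImage":
        """Return a copy with pixels clipped to the declared range."""
        return GrayImage(np.clip(self.pixels, 0.0, self.peak), self.value_range)

    def with_pixels(self, pixels: np.ndarray) -> "GrayImage":
        """Return a new image on the same scale with replaced pixel data."""
        return GrayImage(pixels, self.value_range)


def read_image(path: str) -> GrayImage:
    """Read an 8-bit or 16-bit grayscale PNG/PGM file.

    Multi-channel inputs are reduced to luminance by averaging channels.
    The result is returned on the unit scale.
    """
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        arr = arr.mean(axis=2)
    arr = arr.astype(np.float64)
    # scale by the container's bit depth
    denom = 65535.0 if arr.max() > 255 else 255.0
    return GrayImage(arr / denom, "unit")


def write_image(img: GrayImage, path: str) -> None:
    """Write an image as 8-bit grayscale PNG or PGM (by file extension).

    The image is clipped to its declared range and quantized with
    round-half-away banker's-free rounding; an 8-bit write followed by
    :func:`read_image` is lossless for data that is already 8-bit quantized.
    """
    unit = img.to_unit().clipped()
    data = np.rint(unit.pixels * 255.0).astype(np.uint8)
    iio.imwrite(path, data)
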