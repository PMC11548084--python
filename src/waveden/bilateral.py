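"""Exact bilateral filter over a square d-diameter neighborhood.

For a pixel at (x, y) the output is the normalized sum

    I_B(x,y) = (1/W_P) * sum_{(x',y') in window}
               I(x',y') * exp(-((x-x')^2+(y-y')^2) / (2 sigma_space^2))
                        * exp(-(I(x,y)-I(x',y'))^2 / (2 sigma_color^2))

with W_P the same sum of weights without the intensity factor — a convex
combination of window intensities, so the output can never leave the input's
intensity range.  No approximation is used: the double sum runs over exactly
the d x d window.

sigma_color is interpreted on the 8-bit intensity scale regardless of the
input's declared range (the filter converts at entry and exit), so published
parameter values in 8-bit units apply directly to unit-range images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image import GrayImage

__all__ = ["BilateralParams", "window_offsets", "bilateral"]


@dataclass(frozen=True)
class BilateralParams:
    """The tunable triple: window diameter and the two kernel widths.

    d is the diameter in pixels of the square neighborhood; sigma_color
    (range kernel width, 8-bit intensity units) controls how dissimilar an
    intensity may be and still contribute; sigma_space (pixel units)
    controls the spatial reach inside the window.
    """

    d: int
    sigma_color: float
    sigma_space: float

    def __post_init__(self) -> None:
        if int(self.d) != self.d or self.d < 1:
            raise ValueError("d must be a positive integer")
        object.__setattr__(self, "d", int(self.d))
        if self.sigma_color <= 0 or self.sigma_space <= 0:
            raise ValueError("sigma_color and sigma_space must be strictly positive")


def window_offsets(d: int) -> list[tuple[int, int]]:
    """(dy, dx) offsets of the square window of side d.

    Odd d is centred symmetrically (-d//2 .. d//2).  Even d uses the
    truncated convention -d/2 .. d/2 - 1 on each axis, i.e. the window
    extends one pixel further up/left than down/right, matching the common
    practice of widely used implementations for even apertures.
    """
    if d < 1:
        raise ValueError("d must be >= 1")
    if d % 2:
        r = d // 2
        rng = range(-r, r + 1)
    else:
        rng = range(-d // 2, d // 2)
    return [(dy, dx) for dy in rng for dx in rng]


def bilateral(img: GrayImage, p: BilateralParams) -> GrayImage:
    """Apply the exact bilateral sum with mirror (symmetric) border padding."""
    offsets = window_offsets(p.d)
    work = img.to_eight_bit().pixels
    h, w = work.shape
    pad = max(max(abs(dy), abs(dx)) for dy, dx in offsets)
    padded = np.pad(work, pad, mode="symmetric") if pad else work

    inv2ss = 1.0 / (2.0 * p.sigma_space**2)
    inv2sc = 1.0 / (2.0 * p.sigma_color**2)
    num = np.zeros_like(work)
    den = np.zeros_like(work)
    for dy, dx in offsets:
        shifted = padded[pad + dy : pad + dy + h, pad + dx : pad + dx + w]
        w_spatial = np.exp(-(dy * dy + dx * dx) * inv2ss)
        weight = w_spatial * np.exp(-((work - shifted) ** 2) * inv2sc)
        num += weight * shifted
        den += weight
    out = GrayImage(num / den, "eight_bit")
    return out if img.value_range == "eight_bit" else out.to_unit()
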