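"""Ultrasound-like grayscale phantoms and imaging-noise models.

The generator produces piecewise-smooth phantoms that mimic the geometry of a
B-mode breast ultrasound frame: a dark background, a bright fan-shaped
insonified sector with a gentle depth-dependent intensity falloff, and
elliptical lesion inclusions of differing brightness.  Phantoms have edges,
curved boundaries and flat regions — the features a shrinkage-plus-bilateral
pipeline must both smooth and preserve — without modelling speckle physics.

Two corruption models are provided, matching common medical-imaging noise:

* additive Gaussian noise, parameterized on the 8-bit intensity scale
  (default mean 0, standard deviation 25), and
* Poisson (shot) noise where each pixel is drawn from a Poisson law whose
  mean equals the pixel's own intensity expressed in counts; for unit-range
  images the intensity is scaled by a peak-count parameter (default 255) so
  that lambda = pixel * peak, and the draw is scaled back down.

All generators are pure functions of their arguments and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .image import GrayImage

__all__ = ["NoiseSpec", "make_phantom", "add_gaussian_noise", "add_poisson_noise", "add_noise"]


@dataclass(frozen=True)
class NoiseSpec:
    """Noise model selector.

    ``gaussian_mean``/``gaussian_std`` are on the 8-bit intensity scale and
    are ignored when ``kind == "poisson"``.  The same (spec, seed, clean
    image) always reproduces the identical noisy image.
    """

    kind: str  # "gaussian" | "poisson"
    gaussian_mean: float = 0.0
    gaussian_std: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "poisson"):
            raise ValueError(f"kind must be 'gaussian' or 'poisson', got {self.kind!r}")
        if self.kind == "gaussian" and self.gaussian_std < 0:
            raise ValueError("gaussian_std must be non-negative")


def make_phantom(height: int, width: int, n_lesions: int, seed: int) -> GrayImage:
    """Generate a unit-range ultrasound-like phantom.

    The image contains a dark background (~0.06), a bright fan-shaped sector
    opening downward from the top edge with intensity falling off with depth,
    and ``n_lesions`` elliptical inclusions at randomized positions, sizes,
    orientations and intensity offsets (alternately darker and brighter than
    the surrounding tissue).  A light Gaussian smoothing keeps boundaries
    curved rather than aliased.  Deterministic per seed.
    """
    if height < 32 or width < 32:
        raise ValueError(f"phantom must be at least 32x32, got {height}x{width}")
    if n_lesions < 0:
        raise ValueError("n_lesions must be non-negative")
    rng = np.random.default_rng(seed)

    yy, xx = np.mgrid[0:height, 0:width].astype(np.float64)
    img = np.full((height, width), 0.06)

    # fan-shaped sector: apex above the top edge at the horizontal centre
    apex_y = -0.15 * height
    apex_x = width / 2.0 + rng.uniform(-0.05, 0.05) * width
    dy = yy - apex_y
    dx = xx - apex_x
    radius = np.hypot(dx, dy)
    angle = np.arctan2(dx, dy)  # 0 along straight-down
    half_angle = np.deg2rad(rng.uniform(32.0, 42.0))
    r_max = 1.08 * np.hypot(height - apex_y, 0.5 * width)
    in_fan = (np.abs(angle) < half_angle) & (radius < r_max)
    # tissue brightness decays smoothly with depth (attenuation-like)
    depth = np.clip(radius / r_max, 0.0, 1.0)
    img = np.where(in_fan, 0.62 - 0.25 * depth, img)

    for k in range(n_lesions):
        cy = rng.uniform(0.25, 0.85) * height
        cx = apex_x + np.tan(rng.uniform(-0.7, 0.7) * half_angle) * (cy - apex_y)
        a = rng.uniform(0.06, 0.16) * min(height, width)
        b = rng.uniform(0.06, 0.16) * min(height, width)
        theta = rng.uniform(0.0, np.pi)
        offset = rng.uniform(0.15, 0.35) * (-1.0 if k % 2 == 0 else 1.0)
        ct, st = np.cos(theta), np.sin(theta)
        u = (xx - cx) * ct + (yy - cy) * st
        v = -(xx - cx) * st + (yy - cy) * ct
        inside = (u / a) ** 2 + (v / b) ** 2 < 1.0
        img = np.where(inside & in_fan, img + offset, img)

    img = gaussian_filter(img, sigma=1.2, mode="nearest")
    return GrayImage(np.clip(img, 0.0, 1.0), "unit")


def add_gaussian_noise(img: GrayImage, spec: NoiseSpec) -> GrayImage:
    """Add i.i.d. Gaussian noise drawn on the 8-bit scale, then clip.

    The image is rescaled to the 8-bit range internally if it is unit-range,
    noise N(mean, std^2) is added per pixel, and the result is clipped to the
    declared range of the input.  ``spec.gaussian_std == 0`` returns the
    input unchanged.
    """
    if spec.kind != "gaussian":
        raise ValueError(f"expected a gaussian NoiseSpec, got kind={spec.kind!r}")
    if spec.gaussian_std == 0.0 and spec.gaussian_mean == 0.0:
        return img  # degenerate noise: bit-identical output, no rescale round-trip
    rng = np.random.default_rng(spec.seed)
    work = img.to_eight_bit().pixels
    noisy = work + rng.normal(spec.gaussian_mean, spec.gaussian_std, size=work.shape)
    out = GrayImage(np.clip(noisy, 0.0, 255.0), "eight_bit")
    return out if img.value_range == "eight_bit" else out.to_unit()


def add_poisson_noise(img: GrayImage, seed: int, peak: float = 255.0) -> GrayImage:
    """Replace each pixel by a Poisson draw with mean equal to its intensity.

    Intensities are expressed in counts before sampling: for a unit-range
    image lambda = pixel * peak (default peak 255, i.e. the normalized value
    mapped to the 8-bit count scale); for an 8-bit image peak rescaling is a
    no-op when peak=255.  The draw is divided back by the count scaling and
    clipped to the declared range.
    """
    if peak <= 0:
        raise ValueError("peak must be positive")
    pix = img.to_unit().pixels
    if np.any(pix < 0):
        raise ValueError("Poisson noise requires non-negative intensities")
    rng = np.random.default_rng(seed)
    lam = pix * peak
    counts = rng.poisson(lam).astype(np.float64)
    out = GrayImage(np.clip(counts / peak, 0.0, 1.0), "unit")
    return out if img.value_range == "unit" else out.to_eight_bit()


def add_noise(img: GrayImage, spec: NoiseSpec) -> GrayImage:
    """Dispatch on ``spec.kind``; the seed always comes from the spec."""
    if spec.kind == "gaussian":
        return add_gaussian_noise(img, spec)
    return add_poisson_noise(img, spec.seed)
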