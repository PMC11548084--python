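"""Multilevel wavelet shrinkage denoising (db2, BayesShrink, soft thresholds).

The denoiser decomposes an image with an orthogonal Daubechies wavelet
(default db2, five levels, symmetric boundary extension), soft-thresholds
every detail band with a BayesShrink threshold, and reconstructs.  The
approximation band is never touched.

BayesShrink sets the per-band threshold T = sigma_n^2 / sigma_x, where
sigma_n is the noise standard deviation estimated once from the finest
diagonal band via the median absolute deviation (MAD / 0.6745), and
sigma_x = sqrt(max(E[w^2] - sigma_n^2, 0)) is the band's estimated signal
deviation under the additive-noise model.  A band whose energy does not
exceed the noise floor (sigma_x = 0) is annihilated by thresholding at its
maximum absolute coefficient.

The forward/inverse transforms delegate to PyWavelets; the shrinkage rule
and its composition are implemented here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt

from .image import GrayImage

__all__ = [
    "WaveletSpec",
    "WaveletPyramid",
    "ShrinkageReport",
    "dwt2_multilevel",
    "idwt2_multilevel",
    "estimate_noise_sigma",
    "bayes_shrink_threshold",
    "soft_threshold",
    "wavelet_denoise",
]

# MAD -> sigma for a zero-mean Gaussian: Phi^{-1}(0.75)
_MAD_SCALE = 0.6745


@dataclass(frozen=True)
class WaveletSpec:
    """Transform settings: orthogonal basis, depth and boundary extension."""

    basis_name: str = "db2"
    levels: int = 5
    boundary_mode: str = "symmetric"

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        try:
            pywt.Wavelet(self.basis_name)
        except ValueError as exc:
            raise ValueError(f"unknown wavelet basis {self.basis_name!r}") from exc


@dataclass
class WaveletPyramid:
    """Multilevel 2-D decomposition.

    ``details[0]`` is the finest level (level 1); each entry is a
    (horizontal, vertical, diagonal) tuple of coefficient grids.
    """

    approx: np.ndarray
    details: list[tuple[np.ndarray, np.ndarray, np.ndarray]]
    spec: WaveletSpec
    original_shape: tuple[int, int]

    @property
    def levels(self) -> int:
        return len(self.details)


@dataclass(frozen=True)
class ShrinkageReport:
    """Noise estimate and the soft threshold applied to each detail band.

    Threshold keys are ``"L{level}_{band}"`` with level 1 the finest and
    band one of H, V, D.
    """

    sigma_noise_hat: float
    thresholds: dict[str, float] = field(default_factory=dict)


def max_levels(img: GrayImage, basis_name: str = "db2") -> int:
    """Deepest decomposition the image size admits.

    Symmetric padding keeps every band computable, so the practical limit is
    when further levels operate almost entirely on padded samples: each level
    roughly halves the band, and padding floors band sides near the filter
    support.  floor(log2(min_side)) + 2 levels keeps at least a few genuine
    samples in the coarsest band (an 8x8 image admits the default 5 levels).
    """
    return int(np.floor(np.log2(min(img.shape)))) + 2


def dwt2_multilevel(img: GrayImage, spec: WaveletSpec = WaveletSpec()) -> WaveletPyramid:
    """Forward multilevel 2-D DWT.

    Raises ``ValueError`` naming the maximum feasible level count when the
    image is too small for ``spec.levels``.
    """
    feasible = max_levels(img, spec.basis_name)
    if spec.levels > feasible:
        raise ValueError(
            f"image of shape {img.shape} supports at most {feasible} "
            f"{spec.basis_name} levels, requested {spec.levels}"
        )
    with warnings.catch_warnings():
        # deeper than pywt's conservative "useful" depth is intentional;
        # symmetric padding keeps the transform exact and invertible
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec2(
            img.pixels, spec.basis_name, mode=spec.boundary_mode, level=spec.levels
        )
    approx = coeffs[0]
    details = [tuple(np.asarray(b) for b in lvl) for lvl in coeffs[1:]]
    details.reverse()  # store finest first
    return WaveletPyramid(approx=np.asarray(approx), details=details, spec=spec, original_shape=img.shape)


def idwt2_multilevel(pyr: WaveletPyramid, value_range: str = "unit") -> GrayImage:
    """Inverse multilevel 2-D DWT back to an image of the original shape."""
    coeffs = [pyr.approx] + [tuple(lvl) for lvl in reversed(pyr.details)]
    try:
        rec = pywt.waverec2(coeffs, pyr.spec.basis_name, mode=pyr.spec.boundary_mode)
    except ValueError as exc:
        raise ValueError(f"inconsistent pyramid band shapes: {exc}") from exc
    h, w = pyr.original_shape
    if rec.shape[0] < h or rec.shape[1] < w:
        raise ValueError(f"inconsistent pyramid: reconstruction {rec.shape} smaller than {pyr.original_shape}")
    return GrayImage(rec[:h, :w], value_range)


def estimate_noise_sigma(pyr: WaveletPyramid) -> float:
    """Noise sigma from the finest diagonal band: median(|w|) / 0.6745.

    The finest diagonal band is dominated by noise for natural images, so
    its MAD is a robust estimate of the additive-noise standard deviation
    in coefficient units (equal to image units for an orthogonal basis).
    """
    if pyr.levels < 1:
        raise ValueError("pyramid has no detail levels")
    diag = pyr.details[0][2]
    if diag.size == 0:
        raise ValueError("empty diagonal band")
    return float(np.median(np.abs(diag)) / _MAD_SCALE)


def bayes_shrink_threshold(band: np.ndarray, sigma_noise: float) -> float:
    """BayesShrink threshold T = sigma_n^2 / sigma_x for one detail band.

    sigma_x^2 = max(E[w^2] - sigma_n^2, 0) (detail coefficients are treated
    as zero-mean).  When the band carries no signal beyond the noise floor
    (sigma_x = 0), the band's maximum absolute coefficient is returned so
    soft thresholding annihilates it.
    """
    if sigma_noise < 0:
        raise ValueError("sigma_noise must be non-negative")
    band = np.asarray(band, dtype=np.float64)
    if sigma_noise == 0.0:
        return 0.0
    var_band = float(np.mean(band**2))
    sigma_x2 = max(var_band - sigma_noise**2, 0.0)
    if sigma_x2 == 0.0:
        return float(np.max(np.abs(band))) if band.size else 0.0
    return float(sigma_noise**2 / np.sqrt(sigma_x2))


def soft_threshold(coeffs: np.ndarray, T: float) -> np.ndarray:
    """Soft shrinkage w -> sign(w) * max(|w| - T, 0)."""
    if T < 0:
        raise ValueError("threshold must be non-negative")
    coeffs = np.asarray(coeffs, dtype=np.float64)
    return np.sign(coeffs) * np.maximum(np.abs(coeffs) - T, 0.0)


def wavelet_denoise(
    img: GrayImage, spec: WaveletSpec = WaveletSpec()
) -> tuple[GrayImage, ShrinkageReport]:
    """Decompose, BayesShrink-soft-threshold every detail band, reconstruct.

    Returns the denoised image (same declared range, not clipped) and a
    :class:`ShrinkageReport` with the noise estimate and per-band thresholds.
    """
    pyr = dwt2_multilevel(img, spec)
    sigma_n = estimate_noise_sigma(pyr)
    thresholds: dict[str, float] = {}
    new_details = []
    for lvl_idx, bands in enumerate(pyr.details):  # finest first
        shrunk = []
        for band_name, band in zip("HVD", bands):
            T = bayes_shrink_threshold(band, sigma_n)
            thresholds[f"L{lvl_idx + 1}_{band_name}"] = T
            shrunk.append(soft_threshold(band, T))
        new_details.append(tuple(shrunk))
    den_pyr = WaveletPyramid(
        approx=pyr.approx, details=new_details, spec=spec, original_shape=pyr.original_shape
    )
    out = idwt2_multilevel(den_pyr, img.value_range)
    return out, ShrinkageReport(sigma_noise_hat=sigma_n, thresholds=thresholds)
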