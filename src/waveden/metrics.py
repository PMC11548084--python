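"""Reference-based image-quality metrics: MSE, PSNR and SSIM.

All metrics are computed on the unit [0, 1] working range with MAX = 1, so
PSNR = 10 log10(1 / MSE).  Published MSE values of order 1e-4 paired with
PSNR around 30 dB are consistent only on this scale; an 8-bit statement of
MAX = 255 is nominal and equivalent after rescaling both axes.

SSIM is offered in two modes:

* ``global`` (default): the structural-similarity formula evaluated once
  from the five whole-image moments (means, variances, covariance), and
* ``local``: the same formula per sliding uniform window (default 7x7),
  averaged over the valid interior.

Population (denominator N) moments are used throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter

from .image import GrayImage

__all__ = ["SSIMConfig", "QualityReport", "mse", "psnr", "ssim", "evaluate"]


@dataclass(frozen=True)
class SSIMConfig:
    """SSIM stabilization constants and windowing mode.

    c1 = (k1*MAX)^2 and c2 = (k2*MAX)^2 with MAX = 1 on the working range.
    """

    k1: float = 0.01
    k2: float = 0.03
    window: str = "global"  # "global" | "local"
    local_window_size: int = 7

    def __post_init__(self) -> None:
        if self.k1 <= 0 or self.k2 <= 0:
            raise ValueError("k1 and k2 must be positive")
        if self.window not in ("global", "local"):
            raise ValueError("window must be 'global' or 'local'")
        if self.local_window_size < 3 or self.local_window_size % 2 == 0:
            raise ValueError("local_window_size must be an odd integer >= 3")


@dataclass(frozen=True)
class QualityReport:
    """PSNR (dB), MSE (unit-range squared intensity) and SSIM for a pair."""

    psnr_db: float
    mse: float
    ssim: float

    def to_dict(self) -> dict[str, float]:
        return {"psnr_db": self.psnr_db, "mse": self.mse, "ssim": self.ssim}


def _unit_pair(ref: GrayImage, test: GrayImage) -> tuple[np.ndarray, np.ndarray]:
    if ref.shape != test.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {test.shape}")
    return ref.to_unit().pixels, test.to_unit().pixels


def mse(ref: GrayImage, test: GrayImage) -> float:
    """Mean squared error (1/N) sum (I_i - Ihat_i)^2 on the unit range."""
    a, b = _unit_pair(ref, test)
    return float(np.mean((a - b) ** 2))


def psnr(ref: GrayImage, test: GrayImage) -> float:
    """10 log10(MAX^2 / MSE) with MAX = 1; +inf when the images coincide."""
    m = mse(ref, test)
    if m == 0.0:
        return math.inf
    return 10.0 * math.log10(1.0 / m)


def ssim(ref: GrayImage, test: GrayImage, cfg: SSIMConfig = SSIMConfig()) -> float:
    """Structural similarity index in [-1, 1]; 1 iff the images coincide."""
    x, y = _unit_pair(ref, test)
    c1 = (cfg.k1 * 1.0) ** 2
    c2 = (cfg.k2 * 1.0) ** 2
    if cfg.window == "global":
        mu_x, mu_y = x.mean(), y.mean()
        var_x = x.var()
        var_y = y.var()
        cov = float(np.mean((x - mu_x) * (y - mu_y)))
        return float(
            ((2 * mu_x * mu_y + c1) * (2 * cov + c2))
            / ((mu_x**2 + mu_y**2 + c1) * (var_x + var_y + c2))
        )
    win = cfg.local_window_size
    if min(x.shape) < win:
        raise ValueError(f"image smaller than the {win}x{win} SSIM window")
    mu_x = uniform_filter(x, win)
    mu_y = uniform_filter(y, win)
    var_x = uniform_filter(x * x, win) - mu_x**2
    var_y = uniform_filter(y * y, win) - mu_y**2
    cov = uniform_filter(x * y, win) - mu_x * mu_y
    smap = ((2 * mu_x * mu_y + c1) * (2 * cov + c2)) / (
        (mu_x**2 + mu_y**2 + c1) * (var_x + var_y + c2)
    )
    pad = (win - 1) // 2  # windows touching the border are not fully supported
    return float(smap[pad:-pad, pad:-pad].mean())


def evaluate(ref: GrayImage, test: GrayImage, cfg: SSIMConfig = SSIMConfig()) -> QualityReport:
    """All three metrics, with PSNR derived from the reported MSE."""
    m = mse(ref, test)
    p = math.inf if m == 0.0 else 10.0 * math.log10(1.0 / m)
    return QualityReport(psnr_db=p, mse=m, ssim=ssim(ref, test, cfg))
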