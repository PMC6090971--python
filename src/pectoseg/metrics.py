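"""Image-quality metrics used to rank edge detectors: MSE, PSNR, SSIM.

SSIM is the product of a luminance, a contrast and a structure term,

    L = (2 mu_x mu_y + e1) / (mu_x^2 + mu_y^2 + e1)
    C = (2 s_x s_y  + e2) / (s_x^2  + s_y^2  + e2)
    S = (s_xy + e3)       / (s_x s_y + e3)

raised to exponents alpha, beta, gamma (all 1 by default) and clamped to
[0, 1]. By default the statistics are global over the whole image; a
sliding-window mean is available for parity with common practice. The
stabilization constants default to e1=(0.01*peak)^2, e2=(0.03*peak)^2,
e3=e2/2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError
from .image import BinaryMask, GrayImage, as_array, require_same_shape


@dataclass(frozen=True)
class SSIMParams:
    """Exponents, stabilizers and windowing of the SSIM computation."""

    alpha: float = 1.0
    beta: float = 1.0
    gamma: float = 1.0
    peak: float = 1.0
    eps1: float | None = None  # None -> (0.01*peak)**2
    eps2: float | None = None  # None -> (0.03*peak)**2
    eps3: float | None = None  # None -> eps2 / 2
    window: str = "global"  # {"global", "sliding"}
    window_size: int = 7

    def __post_init__(self) -> None:
        if self.window not in ("global", "sliding"):
            raise ConfigurationError(f"window must be 'global' or 'sliding', got {self.window!r}")
        if self.window_size < 3 or self.window_size % 2 == 0:
            raise ConfigurationError("window_size must be an odd integer >= 3")
        for name in ("eps1", "eps2", "eps3"):
            val = getattr(self, name)
            if val is not None and val <= 0:
                raise ConfigurationError(f"{name} must be > 0")

    def resolved_eps(self) -> tuple[float, float, float]:
        e1 = self.eps1 if self.eps1 is not None else (0.01 * self.peak) ** 2
        e2 = self.eps2 if self.eps2 is not None else (0.03 * self.peak) ** 2
        e3 = self.eps3 if self.eps3 is not None else e2 / 2.0
        return e1, e2, e3


@dataclass(frozen=True)
class QualityReport:
    """MSE (intensity^2), PSNR (dB) and SSIM (dimensionless, [0, 1])."""

    mse: float
    psnr: float
    ssim: float


def mse(ref: GrayImage | np.ndarray, test: GrayImage | np.ndarray) -> float:
    """Mean squared pixelwise difference."""
    require_same_shape(ref, test)
    a, b = as_array(ref), as_array(test)
    return float(np.mean((a - b) ** 2))


def psnr(ref: GrayImage | np.ndarray, test: GrayImage | np.ndarray, peak: float = 1.0) -> float:
    """Peak signal-to-noise ratio 10*log10(peak^2 / MSE), +inf for MSE=0."""
    if peak <= 0:
        raise ConfigurationError(f"peak must be > 0, got {peak}")
    err = mse(ref, test)
    if err == 0.0:
        return math.inf
    return 10.0 * math.log10(peak**2 / err)


def _ssim_terms(
    mu_x: np.ndarray,
    mu_y: np.ndarray,
    var_x: np.ndarray,
    var_y: np.ndarray,
    cov: np.ndarray,
    params: SSIMParams,
) -> np.ndarray:
    e1, e2, e3 = params.resolved_eps()
    sx = np.sqrt(np.maximum(var_x, 0.0))
    sy = np.sqrt(np.maximum(var_y, 0.0))
    lum = (2 * mu_x * mu_y + e1) / (mu_x**2 + mu_y**2 + e1)
    con = (2 * sx * sy + e2) / (var_x + var_y + e2)
    struct = (cov + e3) / (sx * sy + e3)
    signed = (
        np.sign(lum) * np.abs(lum) ** params.alpha
        * np.sign(con) * np.abs(con) ** params.beta
        * np.sign(struct) * np.abs(struct) ** params.gamma
    )
    return signed


def ssim(
    ref: GrayImage | np.ndarray,
    test: GrayImage | np.ndarray,
    params: SSIMParams | None = None,
) -> float:
    """Structural similarity of two same-shape images, clamped to [0, 1].

    ``ssim(x, x) == 1`` for every non-constant x; anti-correlated pairs clamp
    to 0.
    """
    params = params or SSIMParams()
    require_same_shape(ref, test)
    x, y = as_array(ref).astype(float), as_array(test).astype(float)
    if params.window == "global":
        mu_x, mu_y = x.mean(), y.mean()
        var_x, var_y = x.var(), y.var()
        cov = float(np.mean((x - mu_x) * (y - mu_y)))
        val = float(
            _ssim_terms(
                np.float64(mu_x), np.float64(mu_y),
                np.float64(var_x), np.float64(var_y),
                np.float64(cov), params,
            )
        )
    else:
        size = params.window_size
        u = lambda a: ndimage.uniform_filter(a, size=size, mode="reflect")  # noqa: E731
        mu_x, mu_y = u(x), u(y)
        var_x = u(x * x) - mu_x**2
        var_y = u(y * y) - mu_y**2
        cov = u(x * y) - mu_x * mu_y
        val = float(np.mean(_ssim_terms(mu_x, mu_y, var_x, var_y, cov, params)))
    return min(max(val, 0.0), 1.0)


def compare(
    ref: GrayImage | np.ndarray,
    test: GrayImage | np.ndarray,
    peak: float = 1.0,
    ssim_params: SSIMParams | None = None,
) -> QualityReport:
    """Bundle MSE / PSNR / SSIM into one report."""
    return QualityReport(
        mse=mse(ref, test),
        psnr=psnr(ref, test, peak=peak),
        ssim=ssim(ref, test, params=ssim_params),
    )


def edge_image(magnitude: np.ndarray) -> GrayImage:
    """Wrap a normalized gradient magnitude as an image for quality ranking."""
    return GrayImage(np.clip(magnitude, 0.0, 1.0))


__all__ = [
    "SSIMParams",
    "QualityReport",
    "mse",
    "psnr",
    "ssim",
    "compare",
    "edge_image",
]
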