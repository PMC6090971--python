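"""3x3 differential-operator gradients and thresholded edge maps.

The boundary detector is the classic 3x3 mask family: Prewitt by default
(best suited to the predominantly vertical pectoral border) with Sobel as an
option. From the horizontal/vertical difference responses gx, gy the field
carries the Euclidean magnitude sqrt(gx^2 + gy^2), the L1 magnitude
|gx| + |gy|, and the quadrant-aware gradient angle atan2(gx, gy).

The magnitude is globally renormalized to max 1 before thresholding so that
an edge threshold tau in (0, 1) means the same thing across images; gx, gy
and the L1 magnitude are divided by the same factor so the norm relations
``magnitude <= l1_magnitude <= sqrt(2)*magnitude`` survive normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, DegenerateGradientError, ShapeMismatchError
from .image import BinaryMask, GrayImage, as_array

PREWITT_X = np.array([[-1, 0, 1], [-1, 0, 1], [-1, 0, 1]], dtype=float)
PREWITT_Y = PREWITT_X.T.copy()
SOBEL_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float)
SOBEL_Y = SOBEL_X.T.copy()

KERNELS: dict[str, tuple[np.ndarray, np.ndarray]] = {
    "prewitt": (PREWITT_X, PREWITT_Y),
    "sobel": (SOBEL_X, SOBEL_Y),
}


@dataclass(frozen=True)
class GradientField:
    """Per-pixel gradient responses of one image.

    Attributes
    ----------
    gx, gy
        Horizontal / vertical difference responses (normalized, see module
        docstring).
    magnitude
        Euclidean norm sqrt(gx^2+gy^2), renormalized to max 1.
    l1_magnitude
        |gx| + |gy| under the same normalization.
    angle
        Gradient direction atan2(gx, gy) in (-pi, pi]; 0 where the gradient
        vanishes.
    scale
        The pre-normalization maximum magnitude (0 for a constant image);
        multiply by it to recover raw responses.
    """

    gx: np.ndarray
    gy: np.ndarray
    magnitude: np.ndarray
    l1_magnitude: np.ndarray
    angle: np.ndarray
    scale: float


@dataclass(frozen=True)
class EdgeMap:
    """Binary edge raster: pixel is 1 iff magnitude > tau."""

    pixels: BinaryMask
    tau: float


def convolve_3x3(image: GrayImage | np.ndarray, mask: np.ndarray) -> np.ndarray:
    """True 2-D convolution (kernel flipped) with edge-replicated borders.

    Border replication avoids the spurious frame edge that zero padding would
    create where the breast touches the image border.
    """
    kernel = np.asarray(mask, dtype=float)
    if kernel.shape != (3, 3):
        raise ShapeMismatchError(f"kernel must be 3x3, got {kernel.shape}")
    arr = as_array(image).astype(float)
    return ndimage.convolve(arr, kernel, mode="nearest")


def gradient(image: GrayImage, operator: str = "prewitt") -> GradientField:
    """Compute the :class:`GradientField` of an image with a named operator."""
    try:
        kx, ky = KERNELS[operator]
    except KeyError:
        raise ConfigurationError(
            f"unknown operator {operator!r}; expected one of {sorted(KERNELS)}"
        ) from None
    if min(image.shape) < 3:
        raise ShapeMismatchError(
            f"image must be at least 3x3 for a 3x3 mask, got {image.shape}"
        )
    gx = convolve_3x3(image, kx)
    gy = convolve_3x3(image, ky)
    mag = np.hypot(gx, gy)
    scale = float(mag.max())
    # responses at float-rounding level are numerically-flat images; dividing
    # by such a scale would amplify rounding noise into spurious unit edges
    if scale < 1e-12:
        scale = 0.0
        gx = np.zeros_like(gx)
        gy = np.zeros_like(gy)
        mag = np.zeros_like(mag)
    else:
        gx = gx / scale
        gy = gy / scale
        mag = mag / scale
    l1 = np.abs(gx) + np.abs(gy)
    angle = np.arctan2(gx, gy)
    angle[angle == -np.pi] = np.pi  # pin range to (-pi, pi]
    return GradientField(gx=gx, gy=gy, magnitude=mag, l1_magnitude=l1, angle=angle, scale=scale)


def select_threshold(grad: GradientField, edge_fraction: float = 0.10) -> float:
    """Pick tau from the accumulative magnitude histogram.

    tau is the largest value in (0, 1) such that the fraction of pixels with
    magnitude strictly above tau does not exceed ``edge_fraction`` — i.e. the
    pixels with the largest gradients become the edges. When the relevant
    quantile is 0 (large zero-gradient background), tau sits just below the
    smallest positive magnitude so every genuinely non-flat pixel passes.

    Raises
    ------
    DegenerateGradientError
        All magnitudes equal (no threshold in (0, 1) separates anything).
    ConfigurationError
        ``edge_fraction`` outside (0, 1).
    """
    if not 0.0 < edge_fraction < 1.0:
        raise ConfigurationError(f"edge_fraction must lie in (0, 1), got {edge_fraction}")
    m = grad.magnitude.ravel()
    if float(m.max()) == float(m.min()):
        raise DegenerateGradientError("constant gradient magnitude")
    s = np.sort(m)[::-1]
    allowed = int(np.floor(edge_fraction * m.size))
    allowed = min(max(allowed, 1), m.size - 1)
    tau = float(s[allowed])
    if tau <= 0.0:
        smallest_pos = float(m[m > 0].min())
        tau = np.nextafter(smallest_pos, 0.0)
    if tau >= 1.0:
        tau = np.nextafter(1.0, 0.0)
    return tau


def edge_map(grad: GradientField, tau: float) -> EdgeMap:
    """Threshold the normalized magnitude: edge iff magnitude > tau.

    The inequality is strict and tau must lie in the open interval (0, 1).
    """
    if not 0.0 < tau < 1.0:
        raise ConfigurationError(f"tau must lie in (0, 1), got {tau}")
    return EdgeMap(pixels=BinaryMask(grad.magnitude > tau), tau=float(tau))
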