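"""Synthetic MLO mammogram phantoms with exact ground truth.

A phantom emulates the gross radiographic geometry of an MLO view: a dark
background, a bright half-elliptical breast body flush with the chest-wall
border, an even brighter triangular pectoral wedge in the top chest-wall
corner (boundary angle in the anatomical 45-90 degree range, optionally
bowed), small high-intensity label/marker blobs near the opposite border,
and additive Gaussian noise. The masks returned are the exact rasters used
to paint the image before noise, so pipeline output can be scored against
pixel-perfect ground truth without any external data.

What phantoms do *not* emulate: fibroglandular texture, scanner blur,
intensity falloff at the skin line, or X-ray physics. Passing tests on
phantoms therefore demonstrates the geometric/morphological logic of the
pipeline, not clinical-grade performance on real mammograms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace
from typing import Mapping

import numpy as np

from .errors import ConfigurationError
from .image import BinaryMask, GrayImage


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, intensities and noise of one synthetic phantom.

    pectoral_angle
        Angle (degrees) between the pectoral boundary line and the top image
        border, in the anatomical range [45, 90]; 90 degrees is clipped to a
        near-vertical chord.
    curvature
        Bow of the pectoral boundary as a fraction of its top chord length
        (0 = straight line).
    """

    shape: tuple[int, int] = (256, 256)
    orientation: str = "left"
    pectoral_angle: float = 65.0
    pectoral_intensity: float = 0.78
    breast_intensity: float = 0.52
    background_intensity: float = 0.03
    n_labels: int = 2
    label_intensity: float = 0.95
    noise_sigma: float = 0.0
    curvature: float = 0.0
    include_pectoral: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.orientation not in ("left", "right"):
            raise ConfigurationError(f"orientation must be 'left' or 'right', got {self.orientation!r}")
        if not 45.0 <= self.pectoral_angle <= 90.0:
            raise ConfigurationError("pectoral_angle must lie in [45, 90] degrees")
        if not (self.pectoral_intensity > self.breast_intensity > self.background_intensity >= 0.0):
            raise ConfigurationError(
                "intensities must satisfy pectoral > breast > background >= 0"
            )
        if self.pectoral_intensity > 1.0 or self.label_intensity > 1.0:
            raise ConfigurationError("intensities must lie in [0, 1]")
        if self.noise_sigma < 0.0:
            raise ConfigurationError("noise_sigma must be >= 0")
        if self.n_labels < 0:
            raise ConfigurationError("n_labels must be >= 0")
        if min(self.shape) < 32:
            raise ConfigurationError("phantom must be at least 32x32")


@dataclass(frozen=True)
class PhantomOutput:
    """Phantom image plus its exact pre-noise ground-truth masks."""

    image: GrayImage
    breast_gt: BinaryMask      # breast body excluding the pectoral wedge
    pectoral_gt: BinaryMask
    label_gt: BinaryMask
    spec: PhantomSpec


def make_phantom(spec: PhantomSpec | None = None) -> PhantomOutput:
    """Paint one phantom. Deterministic for a fixed spec (seed included)."""
    spec = spec or PhantomSpec()
    h, w = spec.shape
    rng = np.random.default_rng(spec.seed)
    rr, cc = np.mgrid[0:h, 0:w].astype(float)

    # Breast: half-ellipse flush with the left border, reaching the top
    # border near the corner (as the breast does in a well-positioned MLO).
    rc, ar, bc = 0.45 * h, 0.55 * h, 0.60 * w
    breast = ((rr - rc) / ar) ** 2 + (cc / bc) ** 2 <= 1.0

    # Pectoral wedge: boundary chord from (0, c_top) toward (r_bot, 0).
    c_top = 0.30 * w
    angle = math.radians(min(spec.pectoral_angle, 89.0))
    r_bot = min(0.92 * h, c_top * math.tan(angle))
    rows = np.arange(h, dtype=float)
    t = np.clip(rows / r_bot, 0.0, 1.0)
    col_b = c_top * (1.0 - t) + spec.curvature * c_top * np.sin(math.pi * t)
    pect = (rr <= r_bot) & (cc <= col_b[:, None]) & breast
    if not spec.include_pectoral:
        pect[:] = False

    # Labels: small bright rectangles in the background strip far from the
    # breast (cols > 0.78 w).
    label = np.zeros((h, w), dtype=bool)
    for _ in range(spec.n_labels):
        lh = int(rng.integers(max(3, h // 32), max(4, h // 16)))
        lw = int(rng.integers(max(3, w // 32), max(4, w // 16)))
        r0 = int(rng.integers(0, h - lh))
        c0 = int(rng.integers(int(0.80 * w), w - lw))
        label[r0 : r0 + lh, c0 : c0 + lw] = True
    label &= ~breast

    img = np.full((h, w), spec.background_intensity, dtype=float)
    img[breast] = spec.breast_intensity
    img[pect] = spec.pectoral_intensity
    img[label] = spec.label_intensity
    if spec.noise_sigma > 0.0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
        img = np.clip(img, 0.0, 1.0)

    breast_only = breast & ~pect
    if spec.orientation == "right":
        img = np.fliplr(img)
        breast_only = np.fliplr(breast_only)
        pect = np.fliplr(pect)
        label = np.fliplr(label)

    return PhantomOutput(
        image=GrayImage(img),
        breast_gt=BinaryMask(breast_only),
        pectoral_gt=BinaryMask(pect),
        label_gt=BinaryMask(label),
        spec=spec,
    )


_FLOAT_JITTER_FIELDS = {
    "pectoral_angle",
    "pectoral_intensity",
    "breast_intensity",
    "background_intensity",
    "label_intensity",
    "noise_sigma",
    "curvature",
}


def make_cohort(
    n: int,
    base: PhantomSpec | None = None,
    jitter: Mapping[str, tuple[float, float]] | None = None,
    seed: int = 0,
) -> list[PhantomOutput]:
    """Generate ``n`` phantoms with per-field uniform jitter under one seed.

    ``jitter`` maps spec field names to (low, high) ranges sampled uniformly
    and independently per phantom; each phantom also receives its own child
    seed drawn from the master ``seed``.
    """
    if n < 1:
        raise ConfigurationError("cohort size must be >= 1")
    base = base or PhantomSpec()
    jitter = dict(jitter or {})
    valid = {f.name for f in fields(PhantomSpec)}
    for name in jitter:
        if name not in _FLOAT_JITTER_FIELDS:
            raise ConfigurationError(
                f"cannot jitter field {name!r}; jitterable: {sorted(_FLOAT_JITTER_FIELDS & valid)}"
            )
    rng = np.random.default_rng(seed)
    out: list[PhantomOutput] = []
    for _ in range(n):
        draws = {name: float(rng.uniform(lo, hi)) for name, (lo, hi) in jitter.items()}
        child_seed = int(rng.integers(0, 2**31 - 1))
        out.append(make_phantom(replace(base, seed=child_seed, **draws)))
    return out
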