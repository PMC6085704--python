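"""Synthetic inputs with known ground truth.

Two base images — a checkerboard and a smooth "brain-like" phantom of
blurred ellipses — and two families of parameterized large deformations:

* **rotational distortion** (a swirl): pixels inside a disc rotate about its
  center by an angle that decays quadratically to zero at the rim, so the
  warp joins the identity continuously. Strength 1.0 corresponds to a 90°
  rotation at the center.
* **extrusion** (a radial bulge): pixels inside the disc displace radially
  outward by ``strength * d * (1 - r/R)``, again identity at center and rim.

Both are smooth, vanish at the center and on/beyond the radius, and remain
invertible at all supported strengths, so the generated moving image is
itself a valid deformation of the base. Everything is deterministic given
(shape, spec); the seed only drives optional additive intensity noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import ndimage

from .exceptions import ConfigurationError
from .image import DisplacementField, Image, warp

__all__ = [
    "WarpKind",
    "WarpSpec",
    "make_checkerboard",
    "make_phantom",
    "rotational_distortion_field",
    "extrusion_field",
    "warp_field",
    "make_pair",
]

#: swirl angle at the center for strength 1.0 (radians)
THETA_MAX = np.pi / 2


class WarpKind(str, Enum):
    ROTATIONAL_DISTORTION = "rotational_distortion"
    EXTRUSION = "extrusion"


@dataclass
class WarpSpec:
    """Parameters of a synthetic large deformation.

    ``strength`` is the strength percentage / 100 (0.3 = "30%"). ``center``
    and ``radius`` default to the image center and 45% of the smaller image
    side. ``seed`` only affects optional intensity noise, never the warp.
    """

    kind: WarpKind = WarpKind.ROTATIONAL_DISTORTION
    strength: float = 0.5
    center: tuple | None = None
    radius: float | None = None
    seed: int = 0

    def __post_init__(self):
        self.kind = WarpKind(self.kind)
        if not 0.0 <= self.strength <= 1.0:
            raise ConfigurationError(f"strength must be in [0, 1], got {self.strength}")
        if self.radius is not None and self.radius <= 0:
            raise ConfigurationError("radius must be positive")

    def resolved(self, shape) -> tuple[tuple, float]:
        center = self.center if self.center is not None else tuple((s - 1) / 2.0 for s in shape)
        radius = self.radius if self.radius is not None else 0.45 * min(shape)
        return tuple(float(c) for c in center), float(radius)


def make_checkerboard(shape, square_size: int = 8, low: float = 0.0, high: float = 255.0) -> Image:
    """Alternating squares of the two intensities; the top-left square is ``high``."""
    if square_size < 1:
        raise ConfigurationError("square_size must be >= 1")
    idx = np.indices(shape)
    parity = np.sum(idx // square_size, axis=0) % 2
    return Image(np.where(parity == 0, float(high), float(low)))


def make_phantom(shape, noise_sigma: float = 0.0, seed: int = 0) -> Image:
    """A smooth brain-like phantom: a few blurred ellipses with distinct
    intensities on a dark background.

    Unlike the checkerboard it has no large perfectly flat bright regions
    away from edges, so demons forces are informative over most of the
    image. Optional zero-mean Gaussian intensity noise (``noise_sigma`` in
    grey levels) is reproducible via ``seed``.
    """
    shape = tuple(shape)
    rows, cols = np.indices(shape).astype(float)
    cy, cx = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    ry, rx = shape[0] * 0.38, shape[1] * 0.32

    def ellipse(ecy, ecx, ery, erx, angle=0.0):
        dy, dx = rows - ecy, cols - ecx
        ca, sa = np.cos(angle), np.sin(angle)
        y = ca * dy + sa * dx
        x = -sa * dy + ca * dx
        return (y / ery) ** 2 + (x / erx) ** 2 <= 1.0

    img = np.zeros(shape)
    img[ellipse(cy, cx, ry, rx)] = 120.0                                  # head
    img[ellipse(cy, cx, ry * 0.85, rx * 0.85)] = 180.0                    # cortex
    img[ellipse(cy - ry * 0.25, cx - rx * 0.35, ry * 0.28, rx * 0.22, 0.5)] = 90.0
    img[ellipse(cy - ry * 0.25, cx + rx * 0.35, ry * 0.28, rx * 0.22, -0.5)] = 90.0
    img[ellipse(cy + ry * 0.35, cx, ry * 0.18, rx * 0.30)] = 230.0        # bright nucleus
    img[ellipse(cy + ry * 0.05, cx, ry * 0.10, rx * 0.06)] = 40.0         # dark ventricle
    img = ndimage.gaussian_filter(img, sigma=min(shape) / 64.0 + 1.0)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sigma, shape)
    return Image(img)


def rotational_distortion_field(shape, spec: WarpSpec) -> DisplacementField:
    """Swirl displacement: rotation about the center by
    ``theta(r) = strength * THETA_MAX * (1 - r/R)^2`` inside radius R,
    zero outside."""
    if spec.kind is not WarpKind.ROTATIONAL_DISTORTION:
        raise ConfigurationError(f"spec.kind must be rotational_distortion, got {spec.kind}")
    center, radius = spec.resolved(shape)
    dy, dx = (np.indices(shape).astype(float)[i] - center[i] for i in (0, 1))
    r = np.hypot(dy, dx)
    theta = np.where(r < radius, spec.strength * THETA_MAX * (1.0 - r / radius) ** 2, 0.0)
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    new_dy = cos_t * dy - sin_t * dx
    new_dx = sin_t * dy + cos_t * dx
    return DisplacementField(np.stack([new_dy - dy, new_dx - dx]))


def extrusion_field(shape, spec: WarpSpec) -> DisplacementField:
    """Radial bulge: displacement ``strength * d * (1 - r/R)`` inside radius
    R (d the offset from the center), zero outside."""
    if spec.kind is not WarpKind.EXTRUSION:
        raise ConfigurationError(f"spec.kind must be extrusion, got {spec.kind}")
    center, radius = spec.resolved(shape)
    offsets = np.indices(shape).astype(float) - np.asarray(center).reshape(-1, *(1,) * len(shape))
    r = np.sqrt(np.sum(offsets**2, axis=0))
    scale = np.where(r < radius, spec.strength * (1.0 - r / radius), 0.0)
    return DisplacementField(offsets * scale[None, ...])


def warp_field(shape, spec: WarpSpec) -> DisplacementField:
    """Dispatch to the generator for ``spec.kind``."""
    if spec.kind is WarpKind.ROTATIONAL_DISTORTION:
        return rotational_distortion_field(shape, spec)
    return extrusion_field(shape, spec)


def make_pair(base: Image, spec: WarpSpec) -> tuple[Image, Image, DisplacementField]:
    """(fixed, moving, truth): fixed is the base image, moving is the base
    pull-warped by the generated field, truth is that field."""
    truth = warp_field(base.shape, spec)
    moving = warp(base, truth)
    return base, moving, truth
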