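"""Image and vector-field containers, warping, gradients and pyramids.

Conventions used throughout the package:

* arrays are indexed ``(row, col)`` (and ``(plane, row, col)`` in 3D), 0-based;
* displacement and velocity fields store one component per spatial axis in a
  leading component axis, i.e. ``vectors[i]`` is the displacement along array
  axis ``i``, in **pixel units**;
* warping is *pull* (backward): the warped image at pixel ``p`` samples the
  source image at ``p + u(p)``;
* out-of-bounds samples clamp to the nearest edge value.
"""

from __future__ import annotations

from dataclasses import dataclass, field as _dcfield

import numpy as np
from scipy import ndimage

from .exceptions import ConfigurationError, DataError, DimensionError

__all__ = [
    "Image",
    "DisplacementField",
    "VelocityField",
    "warp",
    "gradient",
    "build_pyramid",
    "upsample_field",
]


@dataclass
class Image:
    """A scalar greyscale raster with geometry metadata.

    Parameters
    ----------
    data
        2D (or 3D) array of grey values; converted to float64.
    spacing
        Physical size per pixel along each array axis. Registration itself
        operates in pixel units; spacing is carried for I/O round-trips.
    origin
        World coordinate of pixel (0, 0).
    """

    data: np.ndarray
    spacing: tuple = None
    origin: tuple = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim < 2:
            raise DimensionError(f"image must be at least 2D, got ndim={self.data.ndim}")
        if any(s < 2 for s in self.data.shape):
            raise DimensionError(f"image needs >=2 pixels along every axis, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise DataError("image contains non-finite values")
        if self.spacing is None:
            self.spacing = (1.0,) * self.data.ndim
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != self.data.ndim:
            raise DimensionError("spacing length must equal image dimensionality")
        if any(s <= 0 for s in self.spacing):
            raise ConfigurationError("spacing must be strictly positive")
        if self.origin is None:
            self.origin = (0.0,) * self.data.ndim
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim


def _check_vectors(vectors: np.ndarray) -> np.ndarray:
    vectors = np.asarray(vectors, dtype=np.float64)
    if vectors.ndim < 3 or vectors.shape[0] != vectors.ndim - 1:
        raise DimensionError(
            "field must have shape (ndim, *spatial) with one component per "
            f"spatial axis, got {vectors.shape}"
        )
    if not np.all(np.isfinite(vectors)):
        raise DataError("field contains non-finite components")
    return vectors


@dataclass
class DisplacementField:
    """Per-pixel displacement vectors ``u`` in pixel units, component-first."""

    vectors: np.ndarray

    def __post_init__(self):
        self.vectors = _check_vectors(self.vectors)

    @property
    def spatial_shape(self) -> tuple:
        return self.vectors.shape[1:]

    @property
    def ndim(self) -> int:
        return self.vectors.shape[0]

    @classmethod
    def zeros(cls, shape) -> "DisplacementField":
        shape = tuple(shape)
        return cls(np.zeros((len(shape), *shape)))

    def magnitude(self) -> np.ndarray:
        """Per-pixel Euclidean norm of the vectors."""
        return np.sqrt(np.sum(self.vectors**2, axis=0))


@dataclass
class VelocityField:
    """A stationary velocity field ``v``; its exponential is the deformation."""

    vectors: np.ndarray

    def __post_init__(self):
        self.vectors = _check_vectors(self.vectors)

    @property
    def spatial_shape(self) -> tuple:
        return self.vectors.shape[1:]

    @classmethod
    def zeros(cls, shape) -> "VelocityField":
        shape = tuple(shape)
        return cls(np.zeros((len(shape), *shape)))

    def magnitude(self) -> np.ndarray:
        return np.sqrt(np.sum(self.vectors**2, axis=0))


_INTERP_ORDER = {"linear": 1, "nearest": 0}


def warp(image: Image, field: DisplacementField, interpolation: str = "linear") -> Image:
    """Pull-warp ``image`` by ``field``: output pixel ``p`` takes the value
    ``image(p + field(p))``.

    Out-of-bounds samples clamp to the nearest edge value, which avoids
    injecting artificial zero-intensity edges at the border.
    """
    if field.spatial_shape != image.shape:
        raise DimensionError(
            f"field shape {field.spatial_shape} does not match image shape {image.shape}"
        )
    if interpolation not in _INTERP_ORDER:
        raise ConfigurationError(f"unknown interpolation {interpolation!r}")
    coords = np.indices(image.shape, dtype=np.float64) + field.vectors
    warped = ndimage.map_coordinates(
        image.data, coords, order=_INTERP_ORDER[interpolation], mode="nearest"
    )
    return Image(warped, spacing=image.spacing, origin=image.origin)


def gradient(image: Image) -> np.ndarray:
    """Spatial intensity gradient, shape ``(ndim, *shape)``.

    Central differences in the interior, one-sided at borders; units are
    intensity per pixel (spacing is intentionally not applied — the demons
    formulation here is pixel-based).
    """
    grads = np.gradient(image.data)
    if image.ndim == 1:  # pragma: no cover - Image forbids 1D
        grads = [grads]
    return np.stack(grads, axis=0)


def build_pyramid(image: Image, levels: int) -> list[Image]:
    """Gaussian multi-resolution pyramid, ordered coarse to fine.

    Level ``k`` is the input smoothed (sigma = factor/2) and decimated by
    ``factor = 2**(levels-1-k)``; the finest level is the input itself,
    bit-exactly.
    """
    if levels < 1:
        raise ConfigurationError(f"levels must be >= 1, got {levels}")
    coarsest = 2 ** (levels - 1)
    for s in image.shape:
        if -(-s // coarsest) < 2:  # ceil division
            raise ConfigurationError(
                f"image shape {image.shape} too small for {levels} pyramid levels"
            )
    pyramid = []
    for k in range(levels):
        factor = 2 ** (levels - 1 - k)
        if factor == 1:
            pyramid.append(image)
            continue
        smoothed = ndimage.gaussian_filter(image.data, sigma=factor / 2.0, mode="nearest")
        slicer = tuple(slice(None, None, factor) for _ in image.shape)
        data = smoothed[slicer]
        spacing = tuple(s * factor for s in image.spacing)
        pyramid.append(Image(data, spacing=spacing, origin=image.origin))
    return pyramid


def _resample_component(comp: np.ndarray, target_shape) -> np.ndarray:
    """Linearly interpolate ``comp`` onto ``target_shape`` with aligned corners."""
    src_shape = comp.shape
    axes = []
    for s, t in zip(src_shape, target_shape):
        if t == s:
            axes.append(np.arange(s, dtype=np.float64))
        else:
            axes.append(np.arange(t, dtype=np.float64) * (s - 1) / (t - 1))
    coords = np.meshgrid(*axes, indexing="ij")
    return ndimage.map_coordinates(comp, coords, order=1, mode="nearest")


def upsample_field(field, target_shape):
    """Resample a field to a finer grid, rescaling components to the finer
    grid's pixel units.

    Each component is linearly interpolated to ``target_shape`` and multiplied
    by the per-axis shape ratio, so a displacement that spanned half the
    coarse image still spans half the fine one. Works for both displacement
    and velocity fields (returns the input's type).
    """
    target_shape = tuple(int(t) for t in target_shape)
    src_shape = field.spatial_shape
    if len(target_shape) != len(src_shape):
        raise DimensionError("target dimensionality differs from field dimensionality")
    if any(t < s for s, t in zip(src_shape, target_shape)):
        raise DimensionError(
            f"upsample_field cannot downsample: {src_shape} -> {target_shape}"
        )
    out = np.empty((len(target_shape), *target_shape))
    for i in range(len(target_shape)):
        ratio = target_shape[i] / src_shape[i]
        out[i] = _resample_component(field.vectors[i], target_shape) * ratio
    return type(field)(out)
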