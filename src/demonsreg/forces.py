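"""Demons driving forces: the per-pixel displacement update.

The update at pixel ``p`` is

    u(p) = - (F(p) - M∘t(p)) / (||J_p||^2 + sigma_i(p)^2 / sigma_x^2) * J_p

where ``F`` is the fixed (reference) image, ``M∘t`` the currently warped
moving image, ``sigma_i(p) = |F(p) - M∘t(p)|`` a pointwise noise estimate,
``sigma_x`` the step-length scale, and ``J_p`` the driving-force gradient:

* ``thirion``       — ``J = -∇F`` (fixed-image gradient, the original force);
* ``gauss_newton``  — ``J = -∇(M∘t)`` (warped-moving gradient);
* ``symmetric``     — the mean of the two.

``J^2`` in the denominator is the squared Euclidean norm of the vector
(the standard demons reading). Where both the gradient and the residual
vanish the update is the zero vector: a matched flat pixel has no reason to
move.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .exceptions import ConfigurationError, DataError, DimensionError
from .image import DisplacementField, Image, gradient

__all__ = ["ForceKind", "ForceParams", "local_noise", "select_jacobian", "demons_update"]

#: guards 0/0 at matched flat pixels against floating-point underflow
_DENOM_EPS = 1e-9


class ForceKind(str, Enum):
    THIRION = "thirion"
    GAUSS_NEWTON = "gauss_newton"
    SYMMETRIC = "symmetric"


@dataclass
class ForceParams:
    """Step-length scale sigma_x (dimensionless, > 0); default 1.0."""

    sigma_x: float = 1.0

    def __post_init__(self):
        if not self.sigma_x > 0:
            raise ConfigurationError(f"sigma_x must be > 0, got {self.sigma_x}")


def _check_pair(fixed: Image, warped_moving: Image) -> None:
    if fixed.shape != warped_moving.shape:
        raise DimensionError(
            f"image shapes differ: {fixed.shape} vs {warped_moving.shape}"
        )


def local_noise(fixed: Image, warped_moving: Image) -> np.ndarray:
    """Pointwise noise estimate sigma_i(p) = |F(p) - M∘t(p)|."""
    _check_pair(fixed, warped_moving)
    return np.abs(fixed.data - warped_moving.data)


def select_jacobian(fixed: Image, warped_moving: Image, kind: ForceKind) -> np.ndarray:
    """The driving-force gradient J for the chosen variant, shape (ndim, *shape)."""
    _check_pair(fixed, warped_moving)
    kind = ForceKind(kind)
    if kind is ForceKind.THIRION:
        return -gradient(fixed)
    if kind is ForceKind.GAUSS_NEWTON:
        return -gradient(warped_moving)
    if kind is ForceKind.SYMMETRIC:
        return -(gradient(fixed) + gradient(warped_moving)) / 2.0
    raise ConfigurationError(f"unknown force kind {kind!r}")  # pragma: no cover


def demons_update(
    fixed: Image,
    warped_moving: Image,
    kind: ForceKind = ForceKind.SYMMETRIC,
    params: ForceParams | None = None,
) -> DisplacementField:
    """One demons update step as a displacement field.

    The per-pixel magnitude is bounded by sigma_x / 2 (maximising
    ``|r| ||J|| / (||J||^2 + r^2/sigma_x^2)`` over ``||J||``), which is what
    makes the raw update safe to accumulate.
    """
    _check_pair(fixed, warped_moving)
    if params is None:
        params = ForceParams()
    if not (np.all(np.isfinite(fixed.data)) and np.all(np.isfinite(warped_moving.data))):
        raise DataError("non-finite intensities in demons_update inputs")
    residual = fixed.data - warped_moving.data
    sigma_i = np.abs(residual)
    jac = select_jacobian(fixed, warped_moving, kind)
    denom = np.sum(jac**2, axis=0) + sigma_i**2 / params.sigma_x**2 + _DENOM_EPS
    update = -(residual / denom)[None, ...] * jac
    return DisplacementField(update)
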