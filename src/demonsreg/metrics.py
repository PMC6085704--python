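"""Registration evaluation indexes: MSE, NCC and SSIM.

A note on ``mse``: the evaluation index used here is
``sqrt( sum (S - M)^2 / n )`` — a root-mean-square, despite the customary
name. ``root=False`` gives the conventional (un-rooted) mean squared error
for comparison with other software.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.ndimage import gaussian_filter

from .exceptions import ConfigurationError, DimensionError, MetricUndefinedError
from .image import Image

__all__ = ["MetricReport", "mse", "ncc", "ssim", "evaluate"]


@dataclass
class MetricReport:
    mse: float
    ncc: float
    ssim: float

    def as_dict(self) -> dict:
        return asdict(self)


def _data_pair(reference: Image, result: Image) -> tuple[np.ndarray, np.ndarray]:
    a = reference.data if isinstance(reference, Image) else np.asarray(reference, float)
    b = result.data if isinstance(result, Image) else np.asarray(result, float)
    if a.shape != b.shape:
        raise DimensionError(f"image shapes differ: {a.shape} vs {b.shape}")
    return a, b


def mse(reference: Image, result: Image, root: bool = True) -> float:
    """Root-mean-square intensity error (see module note); ``root=False``
    returns the plain mean squared error."""
    a, b = _data_pair(reference, result)
    m = float(np.mean((a - b) ** 2))
    return float(np.sqrt(m)) if root else m


def ncc(reference: Image, result: Image) -> float:
    """Pearson-form normalized cross-correlation, in [-1, 1].

    Undefined (raises) when either image has zero variance — a constant
    image carries no structure to correlate.
    """
    a, b = _data_pair(reference, result)
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt(np.sum(a**2)) * np.sqrt(np.sum(b**2))
    if denom == 0.0:
        raise MetricUndefinedError("NCC is undefined for zero-variance images")
    return float(np.sum(a * b) / denom)


def ssim(
    reference: Image,
    result: Image,
    data_range: float | None = None,
    sigma: float = 1.5,
    k1: float = 0.01,
    k2: float = 0.03,
) -> float:
    """Mean structural similarity index (Wang et al. construction).

    Local statistics are Gaussian-weighted (sigma=1.5, 11-tap window),
    covariances are population-normalized, and stabilizing constants are
    C1=(k1*L)^2, C2=(k2*L)^2 with L the dynamic range. ``data_range``
    defaults to the reference image's observed range; pass 255 explicitly
    for 8-bit-calibrated comparisons.
    """
    a, b = _data_pair(reference, result)
    truncate = 3.5
    radius = int(truncate * sigma + 0.5)
    win_size = 2 * radius + 1
    if any(s < win_size for s in a.shape):
        raise ConfigurationError(
            f"image shape {a.shape} smaller than the {win_size}-pixel SSIM window; "
            "use a larger image or a smaller sigma"
        )
    if data_range is None:
        data_range = float(a.max() - a.min())
    if data_range <= 0:
        raise MetricUndefinedError("SSIM needs a positive dynamic range")

    blur = dict(sigma=sigma, truncate=truncate, mode="reflect")
    ux = gaussian_filter(a, **blur)
    uy = gaussian_filter(b, **blur)
    uxx = gaussian_filter(a * a, **blur)
    uyy = gaussian_filter(b * b, **blur)
    uxy = gaussian_filter(a * b, **blur)
    vx = uxx - ux * ux
    vy = uyy - uy * uy
    vxy = uxy - ux * uy

    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    s_map = ((2 * ux * uy + c1) * (2 * vxy + c2)) / (
        (ux**2 + uy**2 + c1) * (vx + vy + c2)
    )
    interior = s_map[tuple(slice(radius, dim - radius) for dim in s_map.shape)]
    return float(interior.mean(dtype=np.float64))


def evaluate(reference: Image, result: Image, data_range: float | None = None) -> MetricReport:
    """All three indexes in one report."""
    return MetricReport(
        mse=mse(reference, result),
        ncc=ncc(reference, result),
        ssim=ssim(reference, result, data_range=data_range),
    )
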