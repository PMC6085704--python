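"""Independent brute-force oracles used by the test suite.

Everything here is written as explicit per-pixel loops (or dense small-step
integration), deliberately sharing no code with the library paths it checks.
"""

import numpy as np


def bilinear_sample(data, y, x):
    """Clamped bilinear lookup at a single (possibly fractional) point."""
    h, w = data.shape
    y = min(max(y, 0.0), h - 1.0)
    x = min(max(x, 0.0), w - 1.0)
    y0, x0 = int(np.floor(y)), int(np.floor(x))
    y1, x1 = min(y0 + 1, h - 1), min(x0 + 1, w - 1)
    fy, fx = y - y0, x - x0
    top = data[y0, x0] * (1 - fx) + data[y0, x1] * fx
    bot = data[y1, x0] * (1 - fx) + data[y1, x1] * fx
    return top * (1 - fy) + bot * fy


def warp_loop(data, vectors):
    """Pull-warp by explicit gather: out[p] = data[p + u(p)], bilinear, clamped."""
    out = np.empty_like(data, dtype=float)
    for i in range(data.shape[0]):
        for j in range(data.shape[1]):
            out[i, j] = bilinear_sample(data, i + vectors[0, i, j], j + vectors[1, i, j])
    return out


def gradient_loop(data):
    """Central differences inside, one-sided at borders, per-pixel loops."""
    h, w = data.shape
    gy = np.empty((h, w))
    gx = np.empty((h, w))
    for i in range(h):
        for j in range(w):
            if i == 0:
                gy[i, j] = data[1, j] - data[0, j]
            elif i == h - 1:
                gy[i, j] = data[h - 1, j] - data[h - 2, j]
            else:
                gy[i, j] = (data[i + 1, j] - data[i - 1, j]) / 2.0
            if j == 0:
                gx[i, j] = data[i, 1] - data[i, 0]
            elif j == w - 1:
                gx[i, j] = data[i, w - 1] - data[i, w - 2]
            else:
                gx[i, j] = (data[i, j + 1] - data[i, j - 1]) / 2.0
    return np.stack([gy, gx])


def demons_update_loop(fixed, warped, sigma_x, kind="thirion"):
    """Per-pixel evaluation of the demons update formula."""
    gf = gradient_loop(fixed)
    gm = gradient_loop(warped)
    h, w = fixed.shape
    u = np.zeros((2, h, w))
    for i in range(h):
        for j in range(w):
            r = fixed[i, j] - warped[i, j]
            if kind == "thirion":
                jac = (-gf[0, i, j], -gf[1, i, j])
            elif kind == "gauss_newton":
                jac = (-gm[0, i, j], -gm[1, i, j])
            else:
                jac = (-(gf[0, i, j] + gm[0, i, j]) / 2.0,
                       -(gf[1, i, j] + gm[1, i, j]) / 2.0)
            denom = jac[0] ** 2 + jac[1] ** 2 + (abs(r) ** 2) / sigma_x**2 + 1e-9
            u[0, i, j] = -(r / denom) * jac[0]
            u[1, i, j] = -(r / denom) * jac[1]
    return u


def energy_loop(fixed, warped):
    total = 0.0
    for i in range(fixed.shape[0]):
        for j in range(fixed.shape[1]):
            total += (fixed[i, j] - warped[i, j]) ** 2
    return total / (2.0 * fixed.size)


def rms_error_loop(a, b):
    total = 0.0
    for i in range(a.shape[0]):
        for j in range(a.shape[1]):
            total += (a[i, j] - b[i, j]) ** 2
    return np.sqrt(total / a.size)


def ncc_loop(a, b):
    am, bm = a.mean(), b.mean()
    num = sa = sb = 0.0
    for i in range(a.shape[0]):
        for j in range(a.shape[1]):
            da, db = a[i, j] - am, b[i, j] - bm
            num += da * db
            sa += da * da
            sb += db * db
    return num / (np.sqrt(sa) * np.sqrt(sb))


def compose_loop(outer, inner):
    """result(p) = inner(p) + outer(p + inner(p)) by explicit gather."""
    out = np.empty_like(inner)
    for i in range(inner.shape[1]):
        for j in range(inner.shape[2]):
            y = i + inner[0, i, j]
            x = j + inner[1, i, j]
            out[0, i, j] = inner[0, i, j] + bilinear_sample(outer[0], y, x)
            out[1, i, j] = inner[1, i, j] + bilinear_sample(outer[1], y, x)
    return out


def euler_exp(vectors, steps=256):
    """Flow integration of a stationary velocity field with small Euler steps."""
    from scipy import ndimage

    idx = np.indices(vectors.shape[1:], dtype=float)
    phi = np.zeros_like(vectors)
    for _ in range(steps):
        coords = idx + phi
        sampled = np.stack([
            ndimage.map_coordinates(vectors[i], coords, order=1, mode="nearest")
            for i in range(vectors.shape[0])
        ])
        phi = phi + sampled / steps
    return phi
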