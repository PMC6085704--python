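"""The scaling-and-squaring exponential and its fold-free guarantee.

A stationary velocity field v parameterizes a deformation through exp(v):
halve v until every vector is sub-pixel, then self-compose. The resulting
map is invertible — its Jacobian determinant stays positive — and exp(-v)
undoes it to within a small fraction of a pixel.
"""

import numpy as np
from scipy import ndimage

from demonsreg import VelocityField, compose, exp_field, jacobian_determinant
from demonsreg.diffeo import choose_scaling

rng = np.random.default_rng(0)
raw = rng.normal(size=(2, 64, 64))
v = np.stack([ndimage.gaussian_filter(raw[i], 6.0) for i in range(2)])
v = VelocityField(v * (3.0 / np.sqrt((v**2).sum(axis=0)).max()))  # peak 3 px

n = choose_scaling(v)
phi = exp_field(v)
det = jacobian_determinant(phi)
back = compose(phi, exp_field(VelocityField(-v.vectors)))
residual = np.sqrt((back.vectors**2).sum(axis=0))[4:-4, 4:-4].max()

print(f"peak |v|                      : {v.magnitude().max():.3f} px")
print(f"squarings N (0.5 px rule)     : {n}")
print(f"min interior Jacobian det     : {det[2:-2, 2:-2].min():.4f}")
print(f"exp(v) o exp(-v) max residual : {residual:.4f} px")

# A positive Jacobian determinant everywhere means no folding; the tiny
# round-trip residual shows the parameterization is invertible in practice.
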