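# Methods

## Model

Registration seeks a spatial transform `t` minimizing a regularized
grey-value energy between a fixed image `F` and a moving image `M`,

    E(u) = (1/σ_i²) ‖F − M∘(t+u)‖² + (1/σ_x²) ‖u‖² ,

whose per-pixel minimizer (linearizing `M∘(t+u)` in `u`) is the demons
update

    u(p) = − (F(p) − M∘t(p)) / (‖J_p‖² + σ_i²(p)/σ_x²) · J_p ,
    σ_i(p) = |F(p) − M∘t(p)| .

`J_p²` is read as the squared Euclidean norm of the gradient vector — the
standard demons interpretation. The update magnitude is analytically bounded
by `σ_x/2` per iteration, which is what makes raw accumulation safe. Where
both gradient and residual vanish the update is zero (a matched flat pixel
has no reason to move); an epsilon of 1e−9 in the denominator guards
floating-point underflow in that limit.

Three gradients `J_p` are supported: the fixed image's (`thirion`), the
warped moving image's (`gauss_newton`), and their mean (`symmetric`,
default — it consistently stops in the fewest iterations in our sweeps).

All geometry is in pixel units with 0-based `(row, col)` indexing. Warping
is *pull* (backward): output pixel `p` samples the source at `p + u(p)`,
linear interpolation, clamp-to-edge (clamping avoids injecting artificial
zero-intensity edges at the border; it is also the boundary policy of field
composition, so warps and exponentials are mutually consistent).

## Diffeomorphic parameterization

The deformation is `φ = exp(v)`, the time-1 flow of a stationary velocity
field, computed by scaling and squaring: choose the smallest `N` with
`max_p ‖v(p)‖ / 2^N ≤ 0.5` px (capped at 16 with a warning), seed the small
deformation, self-compose `N` times. Because each squaring composes a map
with itself, folding cannot be introduced beyond interpolation error — the
practical guarantee behind the positive-Jacobian property the tests assert.

The seed is the second-order Taylor step of the flow,
`h v + (h²/2)(∇v)v` with `h = 2^−N`. The plain first-order seed `h v` leaves
an O(h) error in the final map — about 0.03 px at the 0.5-px rule for smooth
fields a few pixels strong — while the second-order seed agrees with a dense
(256-step) Euler flow integration to ~1.5e−3 px at no extra squarings.
`seed_order=1` restores the plain seed. The 0.5-px threshold is exposed as
`exp_max_norm`; accuracy is linear in it.

Jacobian determinants use central differences (one-sided at borders).
Border pixels are excluded from positivity assertions: clamped boundary
handling distorts derivatives there.

## Registration loop

Per pyramid level, each iteration: (1) compute the demons update from the
current residual; (2) Gaussian-smooth the update (σ = `gaussian_sigma`,
default 2 px) and add it to the accumulated velocity; (3) Gaussian-smooth
the accumulated velocity with the same σ; (4) exponentiate; (5) warp and
evaluate the energy `E = (1/2|Ω|) Σ (F − M∘t)²`; (6) stop if the relative
improvement `(E(n−1) − E(n))/E(n−1)` falls below `stop_criterium` (default
0.005). The first iteration of a level never triggers the stop test (two
energies are needed); a non-positive previous energy counts as converged. A
`max_iterations` cap (default 200) exists only for degenerate inputs — all
synthetic runs here stop adaptively well below it.

Design choices that were genuinely open:

* **What is smoothed.** Smoothing only the accumulated velocity
  ("diffusion-like") produces a sawtooth near convergence — the update and
  the re-smoothing of converged structure fight each other, and on some
  pairs a level's energy ends above its first iterate. Smoothing the update
  as well ("fluid-like"; `smooth="both"`, the default) damps the oscillation
  to under 0.5% of the level's initial energy in all sweeps while leaving
  recovery quality, Jacobian positivity and force rankings unchanged.
  `smooth="velocity"` and `smooth="update"` remain selectable.
* **Stopping-rule sign.** Written literally, a test of
  `E(n) − E(n−1) < E(n−1)·stop_criterium` fires on any decreasing step; the
  implemented rule is "stop when the *improvement* is below the relative
  threshold", which is the behaviour an adaptive rule needs. The literal
  form is available via `literal_stop=True`.
* **Between levels** the *velocity* (not its exponential) is upsampled —
  linear interpolation plus per-axis rescaling to the finer grid's pixel
  units — so each level continues the parameterization its predecessor
  optimized. Upsampling the exponential instead would require a log map.
* **Energy grids.** Convergence is evaluated on the current level's grid, so
  per-level traces are internally comparable; energies are not comparable
  *across* levels (finer grids retain more high-frequency residual).

The algorithm has no random element: repeated runs are bit-identical.

## Pyramid

Level `k` of `L` is the input smoothed with a Gaussian (σ = factor/2) and
decimated by `factor = 2^(L−1−k)`; the finest level is the input itself,
bit-exactly (no σ=0.5 pre-blur at factor 1). Images must keep ≥ 2 pixels per
axis at the coarsest level.

## Metrics

* `mse` — `sqrt(Σ(S−M)²/n)`: a root-mean-square, kept under its customary
  name; `root=False` gives the conventional un-rooted value.
* `ncc` — Pearson correlation of the intensities; undefined (raises) for
  zero-variance images rather than silently returning 0.
* `ssim` — mean local structural similarity, Wang et al. construction:
  11-tap Gaussian window (σ = 1.5), population covariance normalization,
  `C1 = (0.01 L)²`, `C2 = (0.03 L)²`. The dynamic range `L` defaults to the
  reference image's observed range (pass `data_range=255` for 8-bit-calibrated
  comparisons). The implementation is independent of scikit-image's and is
  cross-checked against it in the tests to 1e−6.

## Synthetic data

The generator emulates two input classes with known ground truth:

* **Bases.** A checkerboard (default 8-px squares, intensities 0/255) and a
  smooth "brain-like" phantom — blurred ellipses at distinct grey levels —
  whose gradients are informative over most of the image. Optional additive
  Gaussian intensity noise (off by default) is seeded and reproducible.
* **Warps.** *Rotational distortion*: rotation about a disc's center by
  `θ(r) = strength · (π/2) · (1 − r/R)²`, zero at the center and outside the
  radius (strength 1.0 ⇒ 90° at the center — a visually large but invertible
  swirl; the swirl is area-preserving, so its true Jacobian determinant
  is 1). *Extrusion*: radial displacement `strength · d · (1 − r/R)`,
  invertible for strength < 1 (radial derivative ≥ 1 − strength). Defaults:
  center of the image, radius 0.45 × the smaller side. Strength is the
  percentage/100 of the standard 30–90% (swirl) and 10–70% (extrusion)
  grids.

What the generator does *not* emulate: scanner physics (bias fields, Rician
noise, partial-volume effects), multi-modality contrast, occlusion or
topology change between acquisitions. Passing tests therefore demonstrate
the algorithm's mechanics — recovery of smooth invertible warps, fold-free
fields, adaptive stopping — not clinical-grade accuracy on real scans.

One measured caveat: the *initial* MSE of a checkerboard swirled at 90% is
slightly *below* the 70% value (the periodic texture aliases onto itself
under large rotation), so strength-monotonicity of the initial error is
asserted on the phantom base; improvement after registration holds on both
bases at every strength.

## Problem sizes and tolerances

The validation suite runs 128×128 images (3 pyramid levels: 32/64/128) over
the full strength grids — comfortably inside a laptop-minute budget while
large enough for three meaningful pyramid levels. Exponential-map checks use
48×48 velocity fields with peak norm 2 px smoothed at σ = 6 px, compared to
a 256-step Euler integration (agreement ≤ 1e−2 px interior), inverse
composition (≤ 0.1 px), and the semigroup identity `exp(2v) = exp(v)∘exp(v)`
(≤ 1e−2 px). Formula-level checks (update, energy, MSE, NCC) match
hand-written per-pixel loop oracles to 1e−12 relative on ≤ 8×8 integer
images. Trace monotonicity is asserted within 1% of each level's initial
(unregistered) energy — the starting value of the decay curve the stopping
rule monitors; anchoring at a level's first post-update iterate would be
meaningless at fine levels, which begin nearly converged.

## Known limitations

* 2D-first: all numerics are dimension-agnostic, but only 2D paths are
  exercised by tests and the CLI.
* Additive velocity accumulation (`v ← v + u`) is first-order; no
  BCH-corrected composition or log-domain symmetric formulation.
* No affine/rigid pre-alignment; images must share a grid.
* Same-modality only — the grey-value energy presumes comparable
  intensities; inputs are not normalized by default (a `--normalize` flag
  rescales to [0, 255]) because the force balance `σ_i/σ_x` is
  intensity-scale dependent.
* The `σ_x/2` step bound means very large translations rely entirely on the
  pyramid's coarse levels; deformations beyond the coarse grid's capture
  range will not be recovered.
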