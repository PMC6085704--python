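# demonsreg

Adaptive diffeomorphic multi-resolution demons registration for
same-modality greyscale images.

Non-rigid registration aligns a *moving* image `M` onto a *fixed* (reference)
image `F` — the everyday problem behind change detection, atlas building and
motion analysis in medical imaging, where the deformation between two scans
of the same subject can be large (breathing, swelling, positioning). The
demons family solves it with per-pixel optical-flow-like forces; `demonsreg`
implements the adaptive, diffeomorphic, multi-resolution variant:

* **Demons forces.** Each iteration the displacement update is

  `u(p) = − (F(p) − M∘t(p)) / (‖J_p‖² + σ_i²(p)/σ_x²) · J_p`

  with pointwise noise estimate `σ_i(p) = |F(p) − M∘t(p)|` and step-length
  scale `σ_x`. Three force variants differ in the gradient `J_p`: Thirion's
  (`−∇F`), Gauss–Newton (`−∇(M∘t)`), and symmetric (their mean, the default).
* **Diffeomorphic parameterization.** The deformation is the exponential
  `φ = exp(v)` of a stationary velocity field `v`, computed by scaling and
  squaring (halve `v` until all vectors are ≤ 0.5 px, then self-compose).
  The resulting map does not fold: its Jacobian determinant stays positive,
  so topology is preserved and the deformation is invertible.
* **Multi-resolution.** Both images are decomposed into a Gaussian pyramid
  (default 3 levels); the rough deformation is found on coarse grids and
  refined on finer ones, which captures large deformations and avoids local
  optima.
* **Adaptive stopping.** Iterations stop automatically when the grey-value
  energy `E = (1/2|Ω|) Σ (F − M∘t)²` improves by less than a relative
  threshold (`stop_criterium`, default 0.005) — no manual iteration count.

Evaluation metrics (root-mean-square intensity error, Pearson normalized
cross-correlation, structural similarity) and a synthetic-data generator
with known ground-truth warps (checkerboard / smooth phantom bases deformed
by parameterized swirl and radial-extrusion warps) are included.

## Worked example

```bash
python examples/01_register_synthetic_pair.py
```

```
initial  MSE   11.313   NCC 0.9884
final    MSE    0.324   NCC 1.0000   SSIM 0.9998
iterations per level (coarse to fine): [31, 28, 27]
```

A 128×128 phantom was swirled at 50% strength and registered back at default
parameters (`G_σ = 2`, `σ_x = 1.0`, 3 levels, `stop_criterium = 0.005`). The
intensity error drops ~35×, correlation reaches 1.0000, and each pyramid
level stopped adaptively after ~30 iterations. The other examples sweep
deformation strength (`02`), compare the three driving forces (`03`), and
demonstrate the fold-free exponential map (`04`).

The same pipeline is scriptable from the shell:

```bash
demonsreg synth --base phantom --warp rotational-distortion --strength 0.5 --out data/
demonsreg register --fixed data/fixed.tiff --moving data/moving.tiff --out out/ --save-trace
demonsreg evaluate --reference data/fixed.tiff --result out/warped.tiff
```

`register` writes the warped image, the displacement field (multi-component
NIfTI, pull convention, pixel units), a per-iteration energy trace (CSV),
metrics (JSON) and a run manifest.

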