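# Methods

This note documents the models, numerical choices and limitations behind
`silact`. It is the design record: every empirical statement here is computed
by the test suite or by `scripts/acceptance.py`.

## Imaging model and projector

The scanner is modelled as the discrete linear system `g = A u`, where `u` is
the pixel image on an `n_rows × n_cols` grid and each row of `A` holds the
exact intersection lengths of one ray with the grid (Siddon's algorithm). Ray
geometry:

* view angles `θ_k = k · range / n_views`, a half-open `[0°, 180°)` sweep;
* detector bin centres symmetric about the projection of the rotation
  centre, offsets `s_j = (j − (n_bins−1)/2) · bin_size`;
* parallel mode: rays along `(−sin θ, cos θ)` through `s_j (cos θ, sin θ)`;
* fan mode: point source at distance SOD from the isocentre, flat detector
  at SDD, bins along the detector tangent. The bundled scanner profile uses
  the published hardware constants (512 bins of 0.831 mm, SOD 483.41 mm,
  SDD 796.49 mm, 512 views over 180°). A flat detector is assumed; the
  curved/flat choice is not fixed by the source hardware description, and
  flat matches the named flat-panel detector.

`A` is materialised per (geometry, grid) pair as a sparse CSR matrix by a
numba kernel (the Siddon traversal assigns each inter-crossing interval to
the cell containing its midpoint, which is robust for rays running exactly
along pixel edges). Back-projection is literally `Aᵀ`, so the adjoint
identity `⟨Av, w⟩ = ⟨v, Aᵀw⟩` holds to machine precision — the tests assert
1e−6 against an independently assembled dense matrix. Degenerate rays
(coincident endpoints) are errors; rays that miss the grid contribute zero.

## Filtered back-projection

FBP is `scale · Aᵀ(ramp(g))`. The ramp filter is the discrete Ram–Lak kernel
(`h[0] = 1/(4τ²)`, `h[n] = −1/(π²n²τ²)` for odd n, zero for even n, τ = bin
size), applied per view in the frequency domain after zero-padding to the
next power of two ≥ 2·n_bins; no apodisation window is applied. The composite
pad–convolve–crop operator is exactly self-adjoint, which the training loss
relies on. One wording caveat: the source description calls the R–L filter a
smoothing step; the Ram–Lak ramp in fact amplifies high frequencies, and the
standard ramp is what is implemented.

The scale factor is `(π / n_views) · (τ² / pixel_size²)`. The first part is
the usual angular quadrature weight; the second converts the Siddon adjoint
(which deposits intersection *lengths* and sums over all rays crossing a
pixel, contributing `pixel_area / τ` per view) into the continuous
back-projection integral, and additionally absorbs the `τ` quadrature step of
the filtering convolution. With detector pitch equal to pixel pitch this
reduces to the textbook `π / n_views`. On a 128×128 disk with 256 views the
forward–FBP round trip lands near 3% RMSE of the disk amplitude (asserted
< 10%), and the error decreases monotonically across 64→128→256 views. Fan
FBP applies the flat-detector cosine pre-weight and reuses the same adjoint
back-projection with the magnification-corrected bin size — adequate for
previews; quantitative experiments in this package use parallel mode.

## Synthetic data

The generator stands in for clinical slices. Phantoms are sums of 5–12
seeded random ellipses (an enclosing body ellipse plus internal structures,
positive additive intensities so images are non-negative), rasterised with
sub-pixel supersampling, plus the standard Shepp-Logan phantom. For
projector validation an analytic parallel-beam sinogram of any ellipse list
is available in closed form (`2ρab√(w² − (s−s₀)²)/w²`); rasterised-and-traced
vs analytic agree within 1% relative RMSE at 512 bins, cross-validating both
paths.

Dataset recipe (per source procedure): normalise the image to [0, 0.255]
(min–max affine; constant images map to zero), forward-project to a 180°
sinogram, normalise to [0, 1], add zero-mean Gaussian noise of variance
2×10⁻⁶, then delete a contiguous angular window per training pair. Choices
the source leaves open, fixed here:

* **Sinogram normalisation** is per-sample division by the maximum; the
  factor is kept on the sample so reconstructions can be mapped back to
  image units for metrics.
* **Noise placement**: noise is added once to the normalised full sinogram;
  the label is the noisy sinogram and the input is its deleted copy. This
  keeps the invariant that input and label agree bit-exactly on measured
  views, and the 2×10⁻⁶ variance is only meaningful on the normalised
  scale. (Noise on raw vs normalised projections is otherwise ambiguous.)
* **Window indexing**: window labels are 1-based degrees. The deleted block
  starts at view `round((start−1)·n_views/range)` and spans
  `round(n_views·span/range)` views. This reproduces both printed anchors —
  window 1°–120° deletes views 0…340 (341 views at 512/180°) and window
  61°–180° deletes exactly the last 341 views — and gives the five training
  windows starts 0, 43, 85, 128, 171. (A floor-based mapping fails the
  second anchor.)
* Deleted views are zero-filled and flagged in an explicit per-view mask;
  the fill value is a representation choice, the mask carries the
  information.
* Test sets default to the mid-range window (46°–165° style); the start is a
  configuration knob, since "the direction X-rays penetrate worst" has no
  analogue for synthetic phantoms.

A 1000-image × 5-window build yields exactly 5000 pairs; all randomness
derives from one root seed and rebuilds are bit-identical.

## Network

The generator is a U-Net: `depth` 4×4 stride-2 convolutions (channel pattern
64, 128, 256, then 512s; leaky-ReLU slope 0.2; batch norm on all but the
outermost and innermost encoder layers) mirrored by `depth` 4×4 stride-2
transposed convolutions with skip concatenations (batch norm + ReLU;
dropout p = 0.5 in the first three decoder layers). Channels after
concatenation are twice the matching encoder layer's. Full scale is
depth 9 on 512×512; a `depth` knob shrinks the ladder for desk-scale
instances (depth 6 at 64×64), preserving the head and tail of the channel
pattern. The printed decoder channel list ends at 64, which cannot emit a
1-channel sinogram directly, so a 1×1 convolution + sigmoid output head maps
64 → 1 and clamps estimates to [0, 1]. The noise `z` of `G(x, z)` is
realised as train-time dropout (the conditional-GAN convention); no separate
noise vector is fed.

The discriminator is fully convolutional on the channel-concatenated
(limited-angle, candidate) pair: five 4×4 layers, 64/128/256/512/1 filters,
strides 2/2/2/1/1, plain ReLU activations (as printed; the leaky variant is
common elsewhere), sigmoid output. On 512×512 input the patch map is 62×62;
the decision is the arithmetic mean of all patch probabilities. The
advertised 64×64 patch size and the receptive field implied by the printed
five layers do not coincide exactly; the printed layers are implemented and
`count_parameters` reports the exact per-tensor ledger. The full-scale
generator + discriminator total ≈ 76.8 M trainable scalars, which does not
reconcile with the published 87.833 M under any bias/normalisation reading
we tried; the ledger, not the headline number, is authoritative here.

All layers are implemented in numpy (im2col + GEMM in NHWC layout, exact
adjoint transposed convolution, fused numba Adam update). Every backward
pass is verified against central finite differences in float64.

## Training

Per batch: one discriminator update maximising
`E log D(x,y) + E log(1 − D(x,G(x,z)))`, then one generator update on
`L_cGAN + λ₁ L_sino + λ₂ L_recon` against the updated discriminator. The
generator's adversarial term defaults to the non-saturating `−log D(x,G)`
(the literal minimax form is selectable); probabilities are clamped at
1e−7 before logs. `L_recon` is computed through the package's differentiable
FBP at the training geometry; since ϕ is linear the gradient w.r.t. the
estimated sinogram is `ϕᵀ sign(ϕ(ŷ) − ϕ(y))/N`, verified against finite
differences. Optimiser: Adam(0.5, 0.999); learning rate 0.002 for the first
half of the epochs, then linear decay to zero. Loss weights default to
λ₁ = 120, λ₂ = 10⁻⁵, the values selected by the sinogram-RMSE grid search
(the harness is `lambda_grid_search`).

Inference (`inpaint`) runs the generator deterministically (dropout off),
clips to [0, 1], and by default pastes the measured views back bit-exactly
so only the deleted block is network output; the raw-output variant is a
flag, since whether measured data should be pasted back before
reconstruction is an open choice.

## Reconstruction

SART-TV alternates one SART sweep
`u ← u + relax · C Aᵀ R (g − A u)` (R, C inverse row/column sums over valid
views only; relaxation 1.0 by default) with `tv_steps` descent steps on
anisotropic TV (ℓ₁ of forward differences, reflective boundary,
ε = 1e−8 smoothing of |·|). The first TV step length is `α · ‖Δu_SART‖`; α
resets each outer iteration and is multiplied by α_s after every TV step
(per-step decay is the default reading of the ambiguous "after each
computation"; per-iteration decay is selectable). A TV step that would
increase TV is halved until it decreases it, so TV is monotone by
construction. Non-negativity is projected after each outer iteration.
Profiles: 15 iterations / 10 TV steps / α = 0.01 / α_s = 0.95 for inpainted
sinograms; 50 iterations / 15 TV steps for raw limited-angle baselines
(α = 0.015 in the real-data profile). On a consistent full-rank 4×4 toy
system, 200 SART sweeps reach the dense pseudo-inverse solution to well
below 1e−4 RMSE.

## Problem sizes and what the desk scale shows

The published experiments use 512×512 clinical images, 5000 training pairs,
batch 64 and 400 epochs on a multi-GPU machine. This package's smoke profile
— chosen as the largest configuration that runs comfortably on a single CPU
— uses 64×64 sinograms (64 views × 64 bins, parallel), a depth-6 generator,
200 training pairs (40 phantoms × 5 windows), batch 8, 12 epochs, and four
held-out phantoms with the 46°–165° deletion window. Clinical-scale PSNR
values are out of reach of synthetic ellipse phantoms and desk-scale
training, and are not claimed.

What does and does not reproduce at this scale:

* **Reproduces.** Sinogram inpainting works: held-out masked-view MAE drops
  roughly sixfold below the zero-fill baseline, and reconstructions from
  the inpainted sinogram beat reconstructions from the zero-filled limited
  sinogram on every metric, by wide margins.
* **Does not reproduce.** The clinical ordering "SI-GAN + SART-TV beats
  SART-TV on the measured views alone" inverts on these phantoms. Sums of
  constant ellipses are exactly the piecewise-constant objects the TV prior
  models, so 50-iteration SART-TV restricted to the 60° of measured views
  reconstructs them nearly perfectly (typical PSNR ≈ 23.7 over 24 held-out
  phantoms), while the GAN route carries the inpainting error into the
  image (≈ 21.8; the baseline wins on 24 of 24 draws, and still wins when
  training is extended to 30 epochs). On textured clinical anatomy the TV
  baseline collapses and the published ordering emerges; that regime cannot
  be emulated by piecewise-constant phantoms. The corresponding acceptance
  test asserts the clinical ordering and is expected to fail on this
  synthetic data; it is kept as an honest record rather than weakened.

What the synthetic data does not emulate: anatomical texture and
inter-patient variability, detector blur, scatter and beam hardening,
polychromatic physics, and the "hard-to-penetrate direction" placement of
real missing-angle acquisitions. Passing tests therefore demonstrate the
correctness of the operators and the end-to-end trainability of the method,
not clinical performance.

## Known limitations

* Fan-beam FBP reuses the Siddon adjoint with cosine pre-weighting rather
  than an exact distance-weighted pixel-driven back-projector; it is a
  preview tool.
* The GAN stack is CPU-bound numpy; full-scale 512×512 training is out of
  scope (the architecture builds and its parameter ledger is tested).
* 2D only; cone-beam/3D geometry is not modelled.
* Batch normalisation uses batch statistics at train time; batch size 1 is
  unsupported for training.
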