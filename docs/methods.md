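# Methods

`dualrecon` implements hybrid dual-domain reconstruction of undersampled
multi-coil cardiac MR images: two small U-Nets — one operating on composite
k-space, one on composite images — cascaded in either order (KI-Net: k-space
net first; IK-Net: image net first) with a multi-coil data-consistency
(MCDC) operation interleaved between and after them.  This note records the
model, the defaults, and the numerical choices; everything quantitative
stated here is computed by the test-suite or by `scripts/acceptance.py`.

## Forward model and conventions

A 2-D complex image `m` is seen by coil `i` as `c_i = S_i ⊙ m`, where the
sensitivity maps `S_i` are jointly normalized to unit root-sum-of-squares
(`Σ_i |S_i|² = 1` at every pixel).  K-space is related to the image domain by
a single package-wide convention: the centered unitary FFT (`fft2c` /
`ifft2c`, DC at index `(Nx//2, Ny//2)`).  Undersampling removes whole
phase-encode lines (the second array axis); a sampling mask is a binary line
vector broadcast along the frequency-encode axis.

The acquisition is retrospective: fully sampled coil k-space multiplied by a
variable-density (VD) mask.  VD masks always sample a central band (default
1/16 of the lines — the self-calibration region) and draw the remaining
budget without replacement with probability proportional to a DC-centered
Gaussian (`sigma` default `0.15·Ny`).  The total number of lines is enforced
to be exactly `round(Ny / AF)` so the achieved acceleration is reproducible;
a Bernoulli per-line scheme would only match the acceleration in expectation.

## Coil operations

* **Walsh estimation** — per pixel, the sensitivity vector is the principal
  eigenvector of the local inter-coil sample correlation matrix, averaged
  over a square block (default 7×7), phase-referenced to coil 0 and
  normalized to unit RSS.  Block averaging suppresses noise but biases the
  estimate where maps curve within the block; with block size 1 the
  correlation matrix is rank-1 and the estimator is exact on noise-free
  data, which is how the exactness tests use it.  At inference on real
  acquisitions, maps are estimated from the fully sampled center band
  (`estimate_maps_from_center`); on simulations the true maps are available
  and are the default during training.
* **Adaptive combination** — the matched filter `Σ_i conj(S_i) c_i`.  With
  unit-RSS maps it inverts the coil expansion exactly, and it defines the
  reference image for every metric in the package.
* **MCDC** — expand the composite through the maps, apply per-coil hard
  data consistency in k-space (acquired samples replace estimates; an
  optional weight in (0,1) blends them), inverse-transform, recombine.
  Properties worth knowing: the true image is a fixed point, full sampling
  recovers the reference exactly, an empty mask is the identity, and each
  pass strictly decreases the k-space misfit on acquired lines.  A single
  pass is **not** an exact projection: sensitivity multiplication does not
  commute with the line projection, so combine-then-re-expand leaves a
  residual on the acquired samples (~1e-2..1e-1 at AF 2 on the 64×64
  benchmark) and iterating MCDC keeps moving the composite.  The operation
  is implemented exactly as the block diagram defines it rather than as an
  iterated projection-onto-convex-sets scheme.

## Networks

Both subnetworks are the same customized U-Net: 10 bias-free 3×3
convolutions (each followed by ReLU then batch normalization) arranged as
2·depth encoder + 2 bottleneck + 2·depth decoder layers (depth 2 by
default), 2×2 max pooling, 2× nearest-neighbor upsampling followed by a 3×3
convolution, skip concatenations, and a final 1×1 convolution + BN with no
activation.  Complex arrays enter as two channels (real, imaginary) after
per-example normalization to unit maximum magnitude; the scale is reapplied
on output.  Weights are initialized from `N(0, 0.05²)` with a seeded
generator; there are no bias terms anywhere.

The network stack is a self-contained NumPy implementation with hand-written
backpropagation (gradient-checked against finite differences to ~1e-7
relative error).  Inference uses BN running statistics, so repeated
inference is bit-deterministic.

**Head calibration.**  The final BN standardizes the head output per batch,
so with default affine parameters (γ=1, β=0) the network starts several
orders of magnitude away from the label scale and RMSProp's sign-like
per-parameter steps take hundreds of updates to close the gap.  Training
therefore initializes γ/β of the head BN to the per-channel std/mean of the
training labels — mathematically equivalent to training against
standardized targets.  Without this the desk-scale budget is spent crawling
toward the output scale and validation behaves erratically.

## Training

Both cascades are trained incrementally: subnetwork 1 alone against its
domain's fully sampled composite labels, then frozen while every training
example is propagated through it plus MCDC (and the domain transform) to
build the stage-2 inputs; subnetwork 2 then trains against its own domain's
labels.  No end-to-end fine-tuning is performed.  Optimization: MSE loss,
RMSProp (ρ=0.9, ε=1e-7), initial learning rate 1e-3 reduced by ×0.1 after
10 epochs without validation improvement, early stopping after 20 stale
epochs with restoration of the best state (weights *and* BN statistics —
restoring weights alone pairs them with later running statistics and
destroys the model).  The 80/20 train/validation split is drawn by volume,
not by frame, to avoid leakage between temporally adjacent cine frames.
Default batch size is 8.

## Synthetic data

Real short-axis cine data are not redistributable, so the generator paints a
cardiac-like scene from randomized ellipses: torso and chest wall, dark
lungs, a bright left-ventricular blood pool inside a darker myocardial ring,
and a second ventricle; magnitudes lie in [0,1] with an exactly-zero
background (≥5% of pixels).  A seeded 2nd-order polynomial phase makes the
real/imaginary channel split nontrivial.  A `phase` parameter contracts the
ventricles through the cardiac cycle for multi-frame volumes.  The classical
Shepp-Logan head phantom is included as a second, independently checkable
reference object (it matches the scikit-image rendering except at
anti-aliased edges).

Receiver coils are circular loops placed uniformly on a ring of radius
`0.6·Nx` pixels (loop radius `0.25·Nx`), lying parallel to the image plane
at a standoff height equal to the loop radius — a surface-coil-array
convention that keeps the wire out of the slice.  The field is the
Biot-Savart sum over ≥64 straight segments; the sensitivity carries `|B|`
with the phase of the transverse components, and the stack is normalized to
unit RSS.  What this generator does **not** emulate: cardiac/respiratory
motion between frames beyond smooth contraction, noise (optional complex
Gaussian only), k-space inhomogeneity, non-Cartesian trajectories, and the
anatomical variability of real cohorts — so passing tests demonstrate the
correctness and the qualitative behavior of the method, not clinical
performance.

## Baselines and metrics

* **Zero-filled**: adaptive combination of the per-coil inverse transforms.
* **CS-MRI**: proximal gradient (ISTA) on
  `½‖M F S y − x‖² + λ‖W y‖₁` with orthonormal db4 wavelets (periodization,
  3 levels).  The forward operator has unit norm (unit-RSS maps, unitary
  FFT, projection mask), so step ≤ 1 guarantees a monotone objective; λ is
  chosen per experiment on a documented 5-point grid (1e-4 … 1e-2).
* **Single-domain U-Net**: the same image-domain network trained on
  (zero-filled, fully sampled) pairs, applied in one pass without MCDC.
* **Metrics**: RMSE/PSNR/SSIM on magnitude images after normalizing both to
  the reference maximum (dynamic range 1); SSIM uses the canonical 11×11
  Gaussian window, σ=1.5, K1=0.01, K2=0.03.  The reference is always the
  adaptive combination of the fully sampled coil images.  Identical images
  give infinite PSNR, which is excluded from summary means with a warning.

## Desk-scale study conditions

The standard benchmark (`dualrecon.benchmark`) uses 200 training and 20
held-out 64×64 cardiac phantoms, 8 coils, AF 2, networks with 8 base
filters, and at most 30 epochs per stage — sized so the full study
(simulation, two-stage training, baselines, evaluation) runs on a single
CPU in minutes while still exercising every component end to end.  Larger
images, more filters and more epochs only change the budget, not the code
paths.

Two caveats about method rankings on this benchmark.  The phantoms are
noiseless and piecewise smooth — the best case for wavelet sparsity — so CS
reaches SSIM ≈ 0.999 here and outranks the learned methods, which it does
not on real noisy cine data.  And the single-pass U-Net baseline, which has
no data-consistency step, can score below zero-filled at this training
budget.  The benchmark therefore supports the checks actually asserted (the
trained cascade and CS each beat zero-filled; every pipeline runs end to
end), not a full ranking of methods.

## Known limitations

* MCDC is a single pass, not a converged projection (see above); cascade
  outputs satisfy data consistency only approximately after the final pass.
* The NumPy training stack is single-threaded and CPU-bound; it is meant
  for method study, not production-scale training.
* Walsh maps inherit a per-pixel phase reference (coil 0); combined images
  are deterministic but their absolute phase is conventional.
* CS uses ISTA for its monotonicity guarantee; accelerated or
  conjugate-gradient solvers would converge faster but are out of scope.
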