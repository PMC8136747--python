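# Methods

## Physical model

At the Larmor frequency ω the B1 transceive phase φ^tr of a spin-echo
acquisition satisfies, under the standard phase-based EPT assumptions
(σ_H ≫ ωε_H, transmit/receive phase symmetry), the convection–reaction
relation in the resistivity τ = 1/σ_H:

    ∇φ^tr·∇τ + τ∇²φ^tr = 2ωμ₀ ,

with μ₀ = 4π×10⁻⁷ N/A² and ω = 2π·128 MHz by default (3 T). Two readings
of this relation drive the package:

* **Inverse reading** (phase known, τ unknown): a linear first-order PDE
  in τ that is convection-dominated and therefore stabilized with an
  artificial diffusion term −c∇²τ before discretization. Central
  differences on a regular grid give one equation per interior ROI voxel;
  references to boundary voxels are eliminated into the right-hand side
  using known boundary τ. The sparse system is solved by direct LU
  (N ≤ 128² is small; no row scaling), or GMRES if configured. τ values
  with |τ| < 10⁻⁶ m/S or τ ≤ 0 are reported as invalid (NaN) and counted.
* **Forward reading** (τ known, phase unknown): the same relation is
  ∇·(τ∇φ) = 2ωμ₀ in divergence form. The synthetic-phase generator
  discretizes *this* form with harmonic-mean face resistivities and
  φ = 0 on the boundary ring. Using a different discretization from the
  inverse solver is deliberate: the forward→inverse round trip then
  cross-checks both codes rather than inverting the same matrix (the two
  stencils coincide exactly wherever τ is locally constant, which the
  round-trip and residual tests exploit).

Grid spacing defaults to 240 mm / 128 = 1.875 mm and all operators work
in SI meters, so conductivities come out in S/m without rescaling.
Conventions: arrays are indexed [row = y, col = x], 0-based.

### Boundary data and the diffusion constant

The boundary resistivity is an explicit argument. When truth is
unavailable the default strategy inverts the algebraic estimate
σ = ∇²φ/(2ωμ₀), median-filters it (3×3, NaN-aware) and takes the nearest
finite value on the boundary ring. The diffusion constant c is applied
exactly as the discretization is written (c multiplies the Laplacian of τ
with Δ in meters); reference values used in the experiments are c = 0.02
(reconstruction from corrupted data), c = 0.005 (whole-ROI defective-data
solves) and c = 10⁻⁴ ("as small as possible") when the PDE solve serves
as the ground-truth generator for training. Increasing c trades contrast
for smoothness; this monotone behavior is asserted in the tests.

## The moving-local-window MLP

Around every admissible voxel r a (2p+1)² window is slid with stride 1
(default side 9, p = 4). The input is the feature family
F_r = {φ, ∂φ/∂x, ∂φ/∂y, ∇²φ} sampled on the window (4·81 = 324 values);
the output is the conductivity patch on the same window. Architecture:
four hidden layers (dense → batch normalization → ReLU), linear output;
loss is mean absolute error plus an L2 kernel penalty (dense weights
only); optimization is Adam with mini-batches of 300 over 150 epochs.
The reference widths are 1024/512/256/128; the bundled synthetic study
uses 256/128/64/32, which reaches the same qualitative behavior at a
fraction of the cost on one CPU. Learning rate 10⁻³ with a ×0.1 step at
2/3 of the epochs. All randomness (init, shuffling, augmentation) comes
from one seed; on a fixed BLAS configuration training is bit-reproducible.

Implementation note: the network is written directly in NumPy
(`mrept.nn`) — forward, batch-norm backward, Adam — and is deliberately
small and readable; it is the package's core and has no framework
dependency.

### Feature handling

* **Derivatives at the mask rim.** Features use edge-aware stencils
  (2nd-order one-sided gradient, shifted second difference) so the
  family is finite over the whole window support; the PDE solver keeps
  the strict central-difference contract (NaN where the stencil leaves
  the mask). This is what makes a (13×13 mask, p = 4) configuration
  yield the full (13−8)² = 25 windows.
* **Phase gauge.** φ^tr enters the physics only through derivatives; its
  level is arbitrary. The raw-phase group is therefore centered per
  window (mean removed) by default, which prevents the network from
  keying on subject- or phantom-specific phase offsets. Disable with
  `center_phase=False`.
* **Standardization.** Inputs are z-scored per feature group with
  training-set statistics stored in the model (the groups span ~6 orders
  of magnitude: rad vs rad/m vs rad/m²). Gradient groups use zero offset
  and one scale shared across the ∂x/∂y pair so that the symmetry
  augmentation (below) commutes with the normalization.
* **Dihedral augmentation.** The physics is isotropic and the grid
  square, so the feature→patch map is exactly equivariant under the 8
  square symmetries. Each training batch is transformed by a random
  dihedral element implemented as an exact index permutation plus
  gradient component swap/sign map (verified in the tests against
  extraction from transformed images). This enforces the symmetry
  without enlarging the stored window set and measurably improves
  generalization to unseen geometries. On by default
  (`TrainConfig.augment_dihedral`).
* **Ablation.** `feature_groups=("phi",)` reproduces the phase-only
  variant; the window-size sweep accepts sides {5, 9, 13, 17, 21} via
  `WindowSpec.from_side`.

### Aggregation of overlapping predictions

With stride 1 a deep-interior voxel r receives (2p+1)² predictions
(the *overlap stack*). Two representative images are formed:

* σ_p^c(r): the value window r predicts at its own center.
* σ_p^w(r): a convex combination over r's own window with non-local-means
  weights w(r,s) = e^(−|σ_p^{w_r}(r) − σ_p^{w_r}(s)|/η(r)) / ζ_r,
  normalized to sum 1. The decay scale η(r) = max(scale · sd(stack at r),
  floor) uses the sample standard deviation (ddof = 1) of the overlap
  stack — a per-voxel noise estimate; voxels with a single value fall
  back to the floor (10⁻⁶ S/m). The proportionality constant defaults to
  1 and is configurable; the weighted sum's support is r's own window
  while η uses the cross-window stack, and the two sources are kept
  distinct on purpose.

## Synthetic study conditions

The bundled study uses four 64×64 phantoms with tissue-like values
(white matter ~0.3, gray matter ~0.6, CSF ~1.8 S/m at 128 MHz): three
training geometries (disks; rectangle + disk; annulus + disk) and one
held-out geometry (rectangle + concentric disks) that never appears in
training. Interfaces are smoothed with a 1.5-voxel Gaussian: measured
phase maps are band-limited by the acquisition point spread (~1.5 voxels
at a 128 matrix), and a perfectly sharp resistivity jump additionally
makes the convection-dominated inverse solve oscillate — the smoothing is
a property of the data being emulated, not a solver workaround. Training
targets are the PDE reconstruction at c = 10⁻⁴ from clean phase (the
best available truth, as in a pipeline without a reference conductivity),
and evaluation is against the generator's true σ, so reported errors
include the ~1% target imperfection.

Corruption emulates two failure modes: i.i.d. Gaussian phase noise
(default std 0.005 rad, a plausible level for a multi-echo combined
phase at the stated acquisition) and localized defective regions
(default: heavy noise at 10× the base std over a small mask), mimicking
low-SNR areas where the magnitude signal vanishes.

What the generator does **not** emulate: full-Maxwell B1 fields of a
physical coil (the phase comes from the 2-D divergence-form relation
itself), transmit/receive phase asymmetry, phase wrapping, B0-related
artifacts, anatomy-shaped ROIs, or 3-D effects. Passing the synthetic
study therefore demonstrates internal consistency of the pipeline and the
locality/noise-suppression properties of the windowed predictor — not
in-vivo accuracy.

## Numerical choices and degenerate inputs

* Multi-echo combination uses magnitude-squared weights over the odd
  echoes; all-zero-magnitude voxels give NaN with a reported count. No
  phase unwrapping is performed anywhere; inputs are assumed unwrapped.
* PSNR uses the reference image's masked maximum as the peak
  (conductivity has no canonical dynamic range); identical images report
  +inf. All metrics exclude NaN voxels and are masked.
* A constant-phase, c = 0 system is singular and is rejected with an
  error; the direct solver attaches a 1-norm condition estimate to the
  result's diagnostics.
* Window datasets order samples row-major by center; predictions are
  stateless (batch-norm running statistics), so permuting a dataset
  permutes the predictions identically.

## Problem sizes

The default test suite trains one 256/128/64/32 model on 9 408 windows
(three 64×64 phantoms) once and shares it across the learning,
noise-suppression and defect-locality checks; the acceptance script
repeats that training from scratch for its own seed. Both finish in a
few minutes on a single CPU.

## Known limitations

* 2-D only; the 3-D discretization is structurally analogous but not
  implemented.
* The held-out-geometry error of the desk-scale model (~0.13 relative
  L2) is dominated by interface voxels; larger and more diverse training
  sets reduce it further.
* The noise-suppression ordering PSNR(σ_p^w) ≥ PSNR(σ_p^c) is a
  statistical property of the trained model; at desk scale it can
  invert for unlucky training seeds.
* η's proportionality constant is a free parameter (default 1); no
  automatic calibration is attempted.
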