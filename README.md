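# mrept — phase-based MR electrical properties tomography with a moving-local-window MLP

Tissue electrical conductivity at the Larmor frequency (~128 MHz at 3 T)
can be imaged with a standard MRI scanner: the B1 transceive phase
φ^tr = φ⁺ + φ⁻ carries the eddy-current signature of the conductivity
σ_H. This package reconstructs σ_H from 2-D transceive phase maps by
three routes and provides everything needed to study them on synthetic
data:

1. **Algebraic estimate** — σ = ∇²φ^tr / (2ωμ₀), valid only under local
   homogeneity (∇σ ≈ 0); fast but artifact-prone at tissue interfaces.
2. **Convection–reaction PDE inversion** — solve, in the resistivity
   τ = 1/σ,

       −c∇²τ + ∇φ^tr·∇τ + τ∇²φ^tr = 2ωμ₀

   over the ROI interior with known boundary τ, discretized with central
   differences into one sparse row per interior voxel (the constant
   diffusion c stabilizes the convection-dominated system). Accurate, but
   global: a small region of defective phase contaminates the whole
   solution.
3. **Moving-local-window MLP (MLW-MLP)** — a multilayer perceptron maps
   the feature family F_r = {φ, ∂φ/∂x, ∂φ/∂y, ∇²φ} on a (2p+1)×(2p+1)
   window (default 9×9) around each voxel to the conductivity patch on
   that window, Eq. σ_p^{w_r} = Φ(F_r). Sliding the window with stride 1
   gives every voxel up to (2p+1)² overlapping predictions, combined
   either by center-picking (σ_p^c) or by non-local-means weighting
   (σ_p^w) with weights e^(−|σ(r)−σ(s)|/η(r)), where the decay scale η(r)
   is proportional to the standard deviation of the multiply-determined
   predictions at r. Being strictly local, the MLW-MLP blocks artifact
   propagation from defective regions and the weighting suppresses noise
   without losing resolution.

The package includes a synthetic-data module (piecewise-smooth
conductivity phantoms with tissue-like values, a divergence-form forward
phase solver, Gaussian phase noise and defective regions), multi-echo
phase combination, PSNR / relative-L2 / ROI-statistics evaluation, MATLAB
.mat and NIfTI I/O, and a CLI. It is aimed at researchers prototyping
phase-based EPT reconstruction and denoising strategies.

## Worked example

```python
import numpy as np
from mrept import (PhantomSpec, SolverConfig, ROIMask, exact_boundary_tau,
                   forward_phase, make_phantom, psnr, rel_l2,
                   solve_sigma_pde, algebraic_sigma)
from mrept.phantom import Disk

# 64x64 two-compartment phantom: CSF-like disk in white-matter background
spec = PhantomSpec(shape=(64, 64), background=0.3,
                   shapes=[Disk(sigma=1.8, cy=32, cx=32, r=14)])
sigma, mask = make_phantom(spec)
phase = forward_phase(sigma, mask)          # synthetic transceive phase
btau = exact_boundary_tau(sigma, mask)      # known boundary resistivity

rec = solve_sigma_pde(phase, mask, SolverConfig(c=1e-4), btau)
alg = algebraic_sigma(phase, mask)

sel = ROIMask(mask.interior() & np.isfinite(rec.values))
sel_a = ROIMask(sel.inside & np.isfinite(alg.values))
print(f"PDE reconstruction:      rel_l2 = {rel_l2(sigma, rec, sel):.4f}, "
      f"PSNR = {psnr(sigma, rec, sel):.2f} dB")
print(f"algebraic reconstruction: rel_l2 = {rel_l2(sigma, alg, sel_a):.4f}, "
      f"PSNR = {psnr(sigma, alg, sel_a):.2f} dB")
```

Output:

```
PDE reconstruction:      rel_l2 = 0.0767, PSNR = 30.02 dB
algebraic reconstruction: rel_l2 = 0.9006, PSNR = 8.62 dB
```

The PDE route recovers the phantom to ~8% overall error (dominated by the
interface band; away from it the error is ~2%), while the algebraic
estimate is destroyed by its local-homogeneity assumption at the
interface.

The full learning study — train the MLW-MLP on three phantom geometries,
predict a held-out fourth under clean, noisy and defective phase — runs
from the command line:

```bash
mrept run-experiment --seed 0 --out reports.json
```

## Module map

| module | contents |
| --- | --- |
| `mrept.fields` | `ScalarField2D`, `ROIMask`, `EchoStack`, `PhysicsConstants`, central-difference gradients/Laplacian, multi-echo phase combination |
| `mrept.pde` | algebraic estimate, sparse assembly of the convection–reaction system, direct/iterative solve, boundary-τ strategies |
| `mrept.phantom` | phantom specs and rasterization, divergence-form forward phase, noise/defect corruption |
| `mrept.mlw` | sliding-window feature extraction, the MLP (`mrept.nn`), training with dihedral augmentation, prediction, model (de)serialization |
| `mrept.aggregate` | overlap stack, σ_p^c, η estimation, σ_p^w |
| `mrept.metrics` | masked PSNR, relative L2, ROI mean±std |
| `mrept.experiment` | the clean/noisy/defective comparison harness |
| `mrept.io`, `mrept.cli` | .mat / NIfTI readers and writers, `mrept` command group |

See `docs/methods.md` for the model assumptions, parameter choices and
known limitations.
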