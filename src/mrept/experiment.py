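"""End-to-end synthetic study: phantoms -> phase -> PDE truth -> MLW-MLP.

This module wires the pieces into the comparison the method is built
around: the global PDE reconstruction versus the locally predicted
center-pick and non-local-means weighted images, under clean, noisy and
defective phase inputs.  The default phantom set and corruption levels
below define the package's reference study conditions; they are documented
in docs/methods.md.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field

import numpy as np

from . import aggregate as agg
from . import metrics, mlw, nn
from .fields import PhysicsConstants, ROIMask, ScalarField2D
from .pde import SolverConfig, solve_sigma_pde
from .phantom import (Annulus, CorruptionSpec, Disk, PhantomSpec, Rectangle,
                      corrupt_phase, exact_boundary_tau, forward_phase,
                      make_phantom)

#: diffusion coefficient used when the PDE solve serves as ground truth
#: ("as small as possible" to avoid biasing absolute values)
GROUND_TRUTH_C = 1e-4

#: base additive phase-noise std, rad (multi-echo combined phase scale)
DEFAULT_NOISE_SIGMA = 0.005


def default_train_specs() -> list:
    """Three 64x64 training phantoms with tissue-like conductivities.

    Values span the reference ranges at 128 MHz: ~0.3 S/m (white matter),
    ~0.6 S/m (gray matter), ~1.8 S/m (CSF).
    """
    return [
        PhantomSpec(shape=(64, 64), background=0.3, smooth_width=1.5,
                    shapes=[Disk(sigma=1.8, cy=32, cx=32, r=14),
                            Disk(sigma=0.6, cy=16, cx=46, r=7)]),
        PhantomSpec(shape=(64, 64), background=0.4, smooth_width=1.5,
                    shapes=[Rectangle(sigma=0.6, y0=12, x0=10, y1=40, x1=30),
                            Disk(sigma=1.5, cy=44, cx=44, r=10)]),
        PhantomSpec(shape=(64, 64), background=0.35, smooth_width=1.5,
                    shapes=[Annulus(sigma=1.6, cy=32, cx=32, r_in=12,
                                    r_out=20),
                            Disk(sigma=0.5, cy=32, cx=32, r=8)]),
    ]


def default_test_spec() -> PhantomSpec:
    """Held-out phantom with a geometry unseen in training."""
    return PhantomSpec(shape=(64, 64), background=0.45, smooth_width=1.5,
                       shapes=[Rectangle(sigma=1.7, y0=36, x0=12,
                                         y1=52, x1=34),
                               Disk(sigma=0.7, cy=22, cx=40, r=11),
                               Disk(sigma=0.3, cy=22, cx=40, r=4)])


@dataclass
class ExperimentConfig:
    train_specs: list = dc_field(default_factory=default_train_specs)
    test_spec: PhantomSpec = dc_field(default_factory=default_test_spec)
    window: mlw.WindowSpec = dc_field(default_factory=mlw.WindowSpec)
    train_config: nn.TrainConfig = dc_field(
        default_factory=lambda: nn.TrainConfig(hidden=(256, 128, 64, 32),
                                               epochs=150, l2=1e-4))
    agg_config: agg.AggregationConfig = dc_field(
        default_factory=agg.AggregationConfig)
    pde_c: float = 0.02                # PDE route on corrupted data
    ground_truth_c: float = GROUND_TRUTH_C
    noise_sigma: float = DEFAULT_NOISE_SIGMA
    defect_size: int = 5
    seed: int = 0


def pde_ground_truth(sigma_true: ScalarField2D, mask: ROIMask,
                     c: float = GROUND_TRUTH_C,
                     consts: PhysicsConstants | None = None):
    """Forward phase + inverse solve with exact boundary tau.

    Returns (phase, sigma_H); this sigma_H plays the role of the training
    target, mirroring a pipeline where the PDE reconstruction from clean
    data is the best available truth.
    """
    consts = consts or PhysicsConstants()
    phase = forward_phase(sigma_true, mask, consts)
    btau = exact_boundary_tau(sigma_true, mask)
    sigma_h = solve_sigma_pde(phase, mask, SolverConfig(c=c), btau, consts)
    return phase, sigma_h


def build_training_set(specs, window: mlw.WindowSpec,
                       ground_truth_c: float = GROUND_TRUTH_C,
                       consts: PhysicsConstants | None = None
                       ) -> mlw.WindowDataset:
    """Extract and concatenate training windows from several phantoms."""
    consts = consts or PhysicsConstants()
    parts = []
    for spec in specs:
        sigma, mask = make_phantom(spec)
        phase, sigma_h = pde_ground_truth(sigma, mask, ground_truth_c,
                                          consts)
        parts.append(mlw.extract_windows(phase, mask, window,
                                         target=sigma_h))
    features = np.concatenate([d.features for d in parts])
    targets = np.concatenate([d.targets for d in parts])
    centers = np.concatenate([d.centers for d in parts])
    return mlw.WindowDataset(features, targets, centers, window,
                             parts[0].feature_groups, parts[0].grid_shape,
                             parts[0].dx, parts[0].dy)


def reconstruct_mlw(model: mlw.TrainedModel, phase: ScalarField2D,
                    mask: ROIMask,
                    agg_config: agg.AggregationConfig | None = None):
    """Predict patches and aggregate; returns (sigma_c, sigma_w, dataset,
    patches)."""
    agg_config = agg_config or agg.AggregationConfig()
    ds = mlw.extract_windows(phase, mask, model.spec)
    patches = mlw.predict(model, ds)
    sigma_c = agg.center_estimate(patches, ds.centers, model.spec,
                                  phase.shape, phase.dx, phase.dy)
    sigma_w = agg.weighted_estimate(patches, ds.centers, model.spec,
                                    phase.shape, agg_config,
                                    dx=phase.dx, dy=phase.dy)
    return sigma_c, sigma_w, ds, patches


def _covered_mask(field: ScalarField2D, mask: ROIMask) -> ROIMask:
    return ROIMask(mask.inside & np.isfinite(field.values))


def run_experiment(config: ExperimentConfig | None = None,
                   model: mlw.TrainedModel | None = None,
                   out_path=None) -> list:
    """Run the clean / noisy / defective comparison on synthetic data.

    For each condition the held-out phantom is reconstructed by the global
    PDE solve and by the trained MLW-MLP (center-pick and weighted), and
    PSNR / relative L2 against the true conductivity are reported on the
    voxels every route covers.  Returns a list of EvalReport.
    """
    config = config or ExperimentConfig()
    consts = PhysicsConstants()
    rng_seed = config.seed

    if model is None:
        ds = build_training_set(config.train_specs, config.window,
                                config.ground_truth_c, consts)
        tc = config.train_config
        tc.seed = rng_seed
        model = mlw.train(ds, tc)

    sigma_true, mask = make_phantom(config.test_spec)
    phase_clean = forward_phase(sigma_true, mask, consts)
    btau = exact_boundary_tau(sigma_true, mask)

    ny, nx = sigma_true.shape
    d = config.defect_size
    defect = np.zeros((ny, nx), dtype=bool)
    defect[ny // 2 - d // 2: ny // 2 - d // 2 + d,
           nx // 4 - d // 2: nx // 4 - d // 2 + d] = True

    conditions = {
        "clean": phase_clean,
        "noisy": corrupt_phase(phase_clean, CorruptionSpec(
            gaussian_sigma=config.noise_sigma, seed=rng_seed)),
        "defective": corrupt_phase(phase_clean, CorruptionSpec(
            gaussian_sigma=config.noise_sigma, defect_regions=[defect],
            seed=rng_seed + 1)),
    }

    reports = []
    for name, phase in conditions.items():
        c = config.ground_truth_c if name == "clean" else config.pde_c
        sigma_pde = solve_sigma_pde(phase, mask, SolverConfig(c=c), btau,
                                    consts)
        sigma_c, sigma_w, _, _ = reconstruct_mlw(model, phase, mask,
                                                 config.agg_config)
        for method, img in (("pde", sigma_pde), ("center", sigma_c),
                            ("weighted", sigma_w)):
            m = _covered_mask(img, mask)
            reports.append(metrics.EvalReport(
                condition=name, method=method,
                psnr=metrics.psnr(sigma_true, img, m),
                rel_l2=metrics.rel_l2(sigma_true, img, m),
                provenance={"seed": rng_seed, "c": c,
                            "noise_sigma": config.noise_sigma
                            if name != "clean" else 0.0}))
    if out_path is not None:
        with open(out_path, "w") as fh:
            json.dump([r.to_dict() for r in reports], fh, indent=2)
    return reports
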