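"""Moving-local-window feature extraction and the MLW-MLP regressor.

Around every admissible voxel r a (2p+1)^2 window is slid with stride 1
(by default).  The feature family on the window is the phase and its
derivatives, F_r = {phi, dphi/dx, dphi/dy, lap(phi)}, flattened group by
group into a vector of length 4*(2p+1)^2 (324 for the default 9x9 window).
The network maps F_r to the conductivity patch on the same window.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field, asdict

import numpy as np

from . import nn
from .fields import ROIMask, ScalarField2D, phase_derivatives

FEATURE_GROUPS = ("phi", "gx", "gy", "lap")


@dataclass
class WindowSpec:
    """Sliding-window geometry: half-width p (side 2p+1) and stride."""

    p: int = 4
    stride: int = 1

    def __post_init__(self):
        if self.p < 1:
            raise ValueError("window half-width p must be >= 1")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")

    @property
    def side(self) -> int:
        return 2 * self.p + 1

    @property
    def n_voxels(self) -> int:
        return self.side ** 2

    @classmethod
    def from_side(cls, side: int, stride: int = 1) -> "WindowSpec":
        if side % 2 == 0 or side < 3:
            raise ValueError("window side must be odd and >= 3")
        return cls(p=(side - 1) // 2, stride=stride)


@dataclass
class WindowDataset:
    """Paired (feature vector, target patch) samples.

    ``features``: (n, G*K) with G feature groups of K = (2p+1)^2 entries
    each, group-major; ``targets``: (n, K) or None; ``centers``: (n, 2)
    (row, col) voxel indices, row-major ordered.
    """

    features: np.ndarray
    targets: np.ndarray | None
    centers: np.ndarray
    spec: WindowSpec
    feature_groups: tuple = FEATURE_GROUPS
    grid_shape: tuple = None
    dx: float = 1.0
    dy: float = 1.0
    center_phase: bool = True

    def __len__(self):
        return self.features.shape[0]

    @property
    def n_groups(self) -> int:
        return len(self.feature_groups)

    def group_slices(self):
        K = self.spec.n_voxels
        return [slice(g * K, (g + 1) * K) for g in range(self.n_groups)]


def admissible_centers(valid: np.ndarray, spec: WindowSpec) -> np.ndarray:
    """Boolean map of centers whose full window lies inside ``valid``."""
    p = spec.p
    ny, nx = valid.shape
    ok = np.zeros_like(valid)
    if ny < spec.side or nx < spec.side:
        return ok
    # erosion by the (2p+1)^2 square via a sliding-window min
    from numpy.lib.stride_tricks import sliding_window_view
    win = sliding_window_view(valid, (spec.side, spec.side))
    ok[p:ny - p, p:nx - p] = win.all(axis=(2, 3))
    if spec.stride > 1:
        keep = np.zeros_like(ok)
        keep[::spec.stride, ::spec.stride] = True
        ok &= keep
    return ok


def extract_windows(phase: ScalarField2D, mask: ROIMask,
                    spec: WindowSpec | None = None,
                    target: ScalarField2D | None = None,
                    feature_groups=FEATURE_GROUPS,
                    center_phase: bool = True) -> WindowDataset:
    """Slide the window over the mask and collect feature/target pairs.

    A center is admissible when the whole window lies inside the mask and
    every feature value on it is finite (derivatives use edge-aware stencils
    so the family extends to the mask rim); with a target given, the target
    patch must be finite too.  Samples are ordered row-major by center.

    ``center_phase`` subtracts each window's mean from its raw-phase group:
    the transceive phase is only defined up to a constant offset (the
    physics enters through its derivatives), and removing the offset keeps
    the network from keying on subject- or phantom-specific phase levels.
    """
    spec = spec or WindowSpec()
    if phase.shape != mask.shape:
        raise ValueError("phase and mask shapes differ")
    gx, gy, lap = phase_derivatives(phase, mask)
    group_fields = {"phi": phase.values, "gx": gx.values,
                    "gy": gy.values, "lap": lap.values}
    unknown = set(feature_groups) - set(group_fields)
    if unknown:
        raise ValueError(f"unknown feature groups {sorted(unknown)}")
    planes = [group_fields[g] for g in feature_groups]

    valid = mask.inside.copy()
    for pl in planes:
        valid &= np.isfinite(pl)
    if target is not None:
        if target.shape != phase.shape:
            raise ValueError("target and phase shapes differ")
        valid &= np.isfinite(target.values)

    ok = admissible_centers(valid, spec)
    ii, jj = np.nonzero(ok)  # row-major
    if ii.size == 0:
        raise ValueError("no admissible window centers")

    from numpy.lib.stride_tricks import sliding_window_view
    p = spec.p
    feats = []
    for g, pl in zip(feature_groups, planes):
        win = sliding_window_view(pl, (spec.side, spec.side))
        block = win[ii - p, jj - p].reshape(ii.size, -1)
        if g == "phi" and center_phase:
            block = block - block.mean(axis=1, keepdims=True)
        feats.append(block)
    features = np.concatenate(feats, axis=1)

    targets = None
    if target is not None:
        twin = sliding_window_view(target.values, (spec.side, spec.side))
        targets = twin[ii - p, jj - p].reshape(ii.size, -1).copy()

    return WindowDataset(features, targets, np.column_stack([ii, jj]),
                         spec, tuple(feature_groups), phase.shape,
                         phase.dx, phase.dy, center_phase)


def _dihedral_ops(side: int):
    """The 8 square symmetries as (patch permutation, gradient mapping).

    Each op is ``(perm, (src_x, sign_x), (src_y, sign_y))``: scalar patches
    (phase, Laplacian, targets) transform by the index permutation alone;
    the gradient pair transforms covariantly, e.g. under a 90-degree
    rotation the new d/dx patch is the permuted d/dy patch and the new
    d/dy patch is the negated permuted d/dx patch.
    """
    base = np.arange(side * side).reshape(side, side)
    ops = []
    for flip in (False, True):
        for k in range(4):
            perm = np.fliplr(base) if flip else base
            perm = np.rot90(perm, k)
            comp_x, sgn_x = "gx", 1
            comp_y, sgn_y = "gy", 1
            if flip:  # x -> -x mirror: gx changes sign
                sgn_x = -1
            for _ in range(k):  # 90-deg CCW: gx' = gy, gy' = -gx
                comp_x, sgn_x, comp_y, sgn_y = comp_y, sgn_y, comp_x, -sgn_x
            ops.append((perm.ravel().copy(), (comp_x, sgn_x),
                        (comp_y, sgn_y)))
    return ops


def make_dihedral_augment(feature_groups, side: int):
    """Batch-augmentation callback applying a random square symmetry.

    The convection-reaction physics is isotropic and the grid square, so
    the feature-to-patch map is exactly equivariant under the dihedral
    group; augmenting enforces that symmetry on the learned map without
    enlarging the stored dataset.
    """
    K = side * side
    groups = tuple(feature_groups)
    gathers = []
    for perm, (cx, sx), (cy, sy) in _dihedral_ops(side):
        src = np.empty(len(groups) * K, dtype=int)
        sgn = np.ones(len(groups) * K)
        for g, name in enumerate(groups):
            if name == "gx":
                src_name, s = cx, sx
            elif name == "gy":
                src_name, s = cy, sy
            else:
                src_name, s = name, 1
            src_g = groups.index(src_name)
            src[g * K:(g + 1) * K] = src_g * K + perm
            sgn[g * K:(g + 1) * K] = s
        gathers.append((src, sgn, perm))

    def augment(xb, yb, rng):
        src, sgn, perm = gathers[rng.integers(len(gathers))]
        return xb[:, src] * sgn, yb[:, perm]

    return augment


@dataclass
class TrainedModel:
    """The trained MLW-MLP map: parameters plus everything needed to apply
    it reproducibly (window spec, feature groups, per-group input
    standardization statistics, training config and loss history)."""

    params: nn.MLPParams
    spec: WindowSpec
    feature_groups: tuple
    group_mean: np.ndarray   # (G,) pooled over window positions and samples
    group_std: np.ndarray    # (G,)
    config: nn.TrainConfig
    history: dict = dc_field(default_factory=dict)
    center_phase: bool = True

    def normalize(self, features: np.ndarray) -> np.ndarray:
        K = self.spec.n_voxels
        out = np.empty_like(features, dtype=float)
        for g in range(len(self.feature_groups)):
            sl = slice(g * K, (g + 1) * K)
            out[:, sl] = (features[:, sl] - self.group_mean[g]) \
                / self.group_std[g]
        return out

    def save(self, path):
        arrays = {"group_mean": self.group_mean, "group_std": self.group_std,
                  "W_out": self.params.W_out, "b_out": self.params.b_out}
        for k in range(len(self.params.Ws)):
            arrays[f"W_{k}"] = self.params.Ws[k]
            arrays[f"gamma_{k}"] = self.params.gammas[k]
            arrays[f"beta_{k}"] = self.params.betas[k]
            arrays[f"rmean_{k}"] = self.params.run_mean[k]
            arrays[f"rvar_{k}"] = self.params.run_var[k]
        meta = {"spec": asdict(self.spec),
                "feature_groups": list(self.feature_groups),
                "config": asdict(self.config),
                "history": self.history,
                "center_phase": self.center_phase,
                "n_hidden": len(self.params.Ws)}
        arrays["meta_json"] = np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        with np.load(path) as z:
            meta = json.loads(bytes(z["meta_json"].tobytes()).decode())
            nh = meta["n_hidden"]
            params = nn.MLPParams(
                Ws=[z[f"W_{k}"] for k in range(nh)],
                gammas=[z[f"gamma_{k}"] for k in range(nh)],
                betas=[z[f"beta_{k}"] for k in range(nh)],
                run_mean=[z[f"rmean_{k}"] for k in range(nh)],
                run_var=[z[f"rvar_{k}"] for k in range(nh)],
                W_out=z["W_out"], b_out=z["b_out"])
            cfg = nn.TrainConfig(**{**meta["config"],
                                    "hidden": tuple(meta["config"]["hidden"])})
            return cls(params, WindowSpec(**meta["spec"]),
                       tuple(meta["feature_groups"]),
                       z["group_mean"], z["group_std"], cfg,
                       meta["history"], meta.get("center_phase", True))


def train(dataset: WindowDataset,
          config: nn.TrainConfig | None = None) -> TrainedModel:
    """Fit the MLW-MLP on a window dataset.

    Inputs are z-scored per feature group with statistics pooled over all
    window positions and training samples (the four groups differ by orders
    of magnitude in scale: rad vs rad/m vs rad/m^2); the statistics are
    stored in the model and reused verbatim at prediction time.
    """
    if dataset.targets is None:
        raise ValueError("dataset has no targets; extract with target=...")
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    config = config or nn.TrainConfig()

    K = dataset.spec.n_voxels
    G = dataset.n_groups
    mean = np.empty(G)
    std = np.empty(G)
    for g, sl in enumerate(dataset.group_slices()):
        block = dataset.features[:, sl]
        if dataset.feature_groups[g] in ("gx", "gy"):
            # gradient groups: zero offset, scale shared across the pair so
            # that the square symmetries (swap, sign flip) commute with the
            # standardization
            mean[g] = 0.0
            std[g] = 1.0  # placeholder, set below
        else:
            mean[g] = block.mean()
            std[g] = max(block.std(), 1e-12)
    grad_idx = [g for g, n in enumerate(dataset.feature_groups)
                if n in ("gx", "gy")]
    if grad_idx:
        sls = dataset.group_slices()
        rms = np.sqrt(np.mean(np.concatenate(
            [dataset.features[:, sls[g]].ravel() for g in grad_idx]) ** 2))
        for g in grad_idx:
            std[g] = max(rms, 1e-12)

    model = TrainedModel(None, dataset.spec, dataset.feature_groups,
                         mean, std, config,
                         center_phase=dataset.center_phase)
    x = model.normalize(dataset.features)
    augment = None
    if config.augment_dihedral:
        augment = make_dihedral_augment(dataset.feature_groups,
                                        dataset.spec.side)
    params, history = nn.fit(x, dataset.targets, config, augment=augment)
    model.params = params
    model.history = history
    return model


def predict(model: TrainedModel, dataset: WindowDataset) -> np.ndarray:
    """Apply the trained map; returns (n_windows, (2p+1)^2) patches."""
    if dataset.spec.side != model.spec.side:
        raise ValueError(f"dataset window side {dataset.spec.side} != "
                         f"model window side {model.spec.side}")
    expected = len(model.feature_groups) * model.spec.n_voxels
    if dataset.features.shape[1] != expected:
        raise ValueError(f"feature length {dataset.features.shape[1]} != "
                         f"expected {expected}")
    if dataset.center_phase != model.center_phase:
        raise ValueError("dataset and model disagree on phase centering")
    x = model.normalize(dataset.features)
    out = nn.predict(model.params, x)
    if not np.isfinite(out).all():
        raise FloatingPointError("non-finite prediction")
    return out
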