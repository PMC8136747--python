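"""From overlapping window patches to a single conductivity image.

With stride 1 every voxel deep inside the ROI is covered by (2p+1)^2
windows, so its conductivity is multiply determined.  Two representative
estimates are built:

* the center-pick image ``sigma_c(r)``: the value each window predicts at
  its own center, and
* the non-local-means weighted image ``sigma_w(r)``: a convex combination
  of the values in r's own window, with weights
  ``w(r, s) = exp(-|v(r) - v(s)| / eta(r)) / Z_r``
  decaying with the conductivity difference rather than spatial distance.

The decay scale ``eta(r)`` is proportional to the standard deviation of
the multiply-determined values at r gathered across *all* windows covering
r (the overlap stack) — a per-voxel noise-level estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fields import ScalarField2D
from .mlw import WindowSpec


@dataclass
class AggregationConfig:
    """eta(r) = max(eta_scale * sd(overlap values at r), eta_floor).

    ``std_ddof`` 1 = sample (default), 0 = population standard deviation.
    """

    eta_scale: float = 1.0
    eta_floor: float = 1e-6   # S/m
    std_ddof: int = 1

    def __post_init__(self):
        if self.eta_scale <= 0 or self.eta_floor <= 0:
            raise ValueError("eta_scale and eta_floor must be positive")
        if self.std_ddof not in (0, 1):
            raise ValueError("std_ddof must be 0 or 1")


@dataclass
class OverlapStack:
    """All (window, offset) contributions scattered to absolute voxels.

    Flat parallel arrays: ``voxel_flat`` (raveled voxel index), ``values``
    (predicted conductivity) and ``window_index`` (which window produced
    the value), plus the grid shape.
    """

    voxel_flat: np.ndarray
    values: np.ndarray
    window_index: np.ndarray
    shape: tuple
    dx: float = 1.0
    dy: float = 1.0

    def counts(self) -> np.ndarray:
        n = int(np.prod(self.shape))
        return np.bincount(self.voxel_flat, minlength=n).reshape(self.shape)

    def std(self, ddof: int = 1) -> np.ndarray:
        """Per-voxel standard deviation; NaN with < ddof+1 values."""
        n = int(np.prod(self.shape))
        cnt = np.bincount(self.voxel_flat, minlength=n).astype(float)
        s1 = np.bincount(self.voxel_flat, weights=self.values, minlength=n)
        s2 = np.bincount(self.voxel_flat, weights=self.values ** 2,
                         minlength=n)
        out = np.full(n, np.nan)
        ok = cnt > ddof
        # two-pass-equivalent variance, clipped against cancellation
        var = np.zeros(n)
        var[ok] = np.maximum(
            (s2[ok] - s1[ok] ** 2 / cnt[ok]) / (cnt[ok] - ddof), 0.0)
        out[ok] = np.sqrt(var[ok])
        out[cnt == 0] = np.nan
        return out.reshape(self.shape)

    def values_at(self, i: int, j: int) -> np.ndarray:
        flat = i * self.shape[1] + j
        return self.values[self.voxel_flat == flat]


def _check_patches(patches, centers, spec: WindowSpec, shape):
    patches = np.asarray(patches, dtype=float)
    centers = np.asarray(centers, dtype=int)
    if patches.ndim != 2 or patches.shape[1] != spec.n_voxels:
        raise ValueError(f"patches must be (n, {spec.n_voxels})")
    if centers.shape != (patches.shape[0], 2):
        raise ValueError("centers must be (n, 2)")
    p = spec.p
    ny, nx = shape
    if ((centers[:, 0] < p).any() or (centers[:, 0] >= ny - p).any()
            or (centers[:, 1] < p).any() or (centers[:, 1] >= nx - p).any()):
        raise ValueError("a window center lies too close to the grid edge")
    return patches, centers


def build_overlap_stack(patches, centers, spec: WindowSpec, shape,
                        dx: float = 1.0, dy: float = 1.0) -> OverlapStack:
    """Scatter every patch entry to its absolute voxel."""
    patches, centers = _check_patches(patches, centers, spec, shape)
    n, K = patches.shape
    side = spec.side
    off = np.arange(side) - spec.p
    oy, ox = np.meshgrid(off, off, indexing="ij")
    oy, ox = oy.ravel(), ox.ravel()
    rows = centers[:, 0][:, None] + oy[None, :]
    cols = centers[:, 1][:, None] + ox[None, :]
    flat = (rows * shape[1] + cols).ravel()
    widx = np.repeat(np.arange(n), K)
    return OverlapStack(flat, patches.ravel().copy(), widx, tuple(shape),
                        dx, dy)


def center_estimate(patches, centers, spec: WindowSpec, shape,
                    dx: float = 1.0, dy: float = 1.0) -> ScalarField2D:
    """sigma_c: each window's value at its own center; NaN elsewhere."""
    patches, centers = _check_patches(patches, centers, spec, shape)
    out = np.full(shape, np.nan)
    mid = spec.p * spec.side + spec.p
    out[centers[:, 0], centers[:, 1]] = patches[:, mid]
    return ScalarField2D(out, dx, dy, units="S/m")


def estimate_eta(stack: OverlapStack,
                 cfg: AggregationConfig | None = None) -> ScalarField2D:
    """Per-voxel weight decay scale from the overlap-stack noise level.

    Voxels with too few values for the chosen std definition fall back to
    the floor; uncovered voxels are NaN.
    """
    cfg = cfg or AggregationConfig()
    sd = stack.std(ddof=cfg.std_ddof)
    covered = stack.counts() > 0
    eta = np.where(np.isfinite(sd),
                   np.maximum(cfg.eta_scale * sd, cfg.eta_floor),
                   cfg.eta_floor)
    eta = np.where(covered, eta, np.nan)
    return ScalarField2D(eta, stack.dx, stack.dy, units="S/m")


def nlm_weights(patches: np.ndarray, spec: WindowSpec,
                eta_r: np.ndarray) -> np.ndarray:
    """Similarity weights within each window, normalized to sum 1.

    ``w[k, s] = exp(-|v_k(center) - v_k(s)| / eta_r[k]) / Z_k`` for patch k.
    """
    patches = np.asarray(patches, dtype=float)
    mid = spec.p * spec.side + spec.p
    d = np.abs(patches - patches[:, mid:mid + 1]) / \
        np.asarray(eta_r, dtype=float)[:, None]
    w = np.exp(-d)
    w /= w.sum(axis=1, keepdims=True)
    return w


def weighted_estimate(patches, centers, spec: WindowSpec, shape,
                      cfg: AggregationConfig | None = None,
                      eta: ScalarField2D | None = None,
                      dx: float = 1.0, dy: float = 1.0) -> ScalarField2D:
    """sigma_w: non-local-means combination inside each window.

    For window r with predicted patch v and center value v_c:
    weights ``exp(-|v_c - v| / eta(r))`` normalized to sum 1; the output at
    r is the weighted sum — always inside [min(v), max(v)].
    """
    cfg = cfg or AggregationConfig()
    patches, centers = _check_patches(patches, centers, spec, shape)
    if eta is None:
        stack = build_overlap_stack(patches, centers, spec, shape, dx, dy)
        eta = estimate_eta(stack, cfg)
    eta_r = eta.values[centers[:, 0], centers[:, 1]]
    if np.any(~np.isfinite(eta_r)) or np.any(eta_r <= 0):
        raise ValueError("eta must be positive and finite at window centers")
    w = nlm_weights(patches, spec, eta_r)
    vals = (w * patches).sum(axis=1)
    out = np.full(shape, np.nan)
    out[centers[:, 0], centers[:, 1]] = vals
    return ScalarField2D(out, dx, dy, units="S/m")
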