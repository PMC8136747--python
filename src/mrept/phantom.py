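"""Synthetic conductivity phantoms and forward phase synthesis.

The forward model solves the divergence form of the phase-based EPT
relation, ``div(tau grad(phi)) = 2 omega mu0`` with ``phi = 0`` on the mask
boundary, discretized with harmonic-mean face resistivities.  This is a
*different* discretization from the inverse solver's non-divergence stencil,
so the forward→inverse round trip is a genuine cross-check rather than an
inverse crime; the two stencils coincide exactly wherever tau is locally
constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage
from scipy.sparse import csr_matrix
from scipy.sparse.linalg import spsolve

from .fields import DEFAULT_SPACING, PhysicsConstants, ROIMask, ScalarField2D

_SIGMA_RANGE = (0.01, 5.0)  # plausible tissue range, S/m


@dataclass
class Shape:
    """Base for phantom inclusions; ``sigma`` in S/m."""

    sigma: float

    def contains(self, yy, xx):  # pragma: no cover - abstract
        raise NotImplementedError


@dataclass
class Disk(Shape):
    cy: float = 0.0
    cx: float = 0.0
    r: float = 1.0

    def contains(self, yy, xx):
        return (yy - self.cy) ** 2 + (xx - self.cx) ** 2 <= self.r ** 2


@dataclass
class Rectangle(Shape):
    y0: float = 0.0
    x0: float = 0.0
    y1: float = 1.0
    x1: float = 1.0

    def contains(self, yy, xx):
        return ((yy >= self.y0) & (yy <= self.y1)
                & (xx >= self.x0) & (xx <= self.x1))


@dataclass
class Annulus(Shape):
    cy: float = 0.0
    cx: float = 0.0
    r_in: float = 1.0
    r_out: float = 2.0

    def contains(self, yy, xx):
        d2 = (yy - self.cy) ** 2 + (xx - self.cx) ** 2
        return (d2 >= self.r_in ** 2) & (d2 <= self.r_out ** 2)


@dataclass
class PhantomSpec:
    """Piecewise-constant conductivity phantom description.

    Shapes are painted over the background in list order (last wins).
    ``smooth_width`` > 0 applies a Gaussian blur of that many voxels to the
    interfaces.  The default of 1.5 voxels mimics the acquisition
    point-spread of a 128-matrix scan: measured phase maps are band-limited,
    so tissue transitions are never single-voxel sharp.
    """

    shape: tuple = (64, 64)
    background: float = 0.3          # S/m, white-matter-like
    shapes: list = dc_field(default_factory=list)
    smooth_width: float = 1.5        # voxels
    seed: int = 0

    def __post_init__(self):
        vals = [self.background] + [s.sigma for s in self.shapes]
        for v in vals:
            if not (_SIGMA_RANGE[0] <= v <= _SIGMA_RANGE[1]):
                raise ValueError(f"sigma {v} outside plausible tissue range "
                                 f"{_SIGMA_RANGE} S/m")


@dataclass
class CorruptionSpec:
    """Additive Gaussian phase noise plus localized defective regions.

    ``gaussian_sigma`` is the i.i.d. phase noise std in radians.  Defect
    regions (boolean masks) are overwritten according to ``defect_mode``:
    ``heavy_noise`` adds noise of std ``defect_noise_scale * gaussian_sigma``
    (or ``defect_sigma`` if given), ``zero_phase`` zeroes the phase.
    """

    gaussian_sigma: float = 0.0
    defect_regions: list = dc_field(default_factory=list)
    defect_mode: str = "heavy_noise"
    defect_noise_scale: float = 10.0
    defect_sigma: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.gaussian_sigma < 0:
            raise ValueError("gaussian_sigma must be >= 0")
        if self.defect_mode not in ("heavy_noise", "zero_phase"):
            raise ValueError(f"unknown defect mode {self.defect_mode!r}")


def make_phantom(spec: PhantomSpec, dx: float = DEFAULT_SPACING,
                 dy: float | None = None):
    """Rasterize a phantom; returns (sigma field in S/m, full-grid ROI mask).

    Deterministic given the spec.  Shape membership is evaluated at voxel
    centers (indices), so coordinates in ``spec.shapes`` are in voxel units.
    """
    dy = dx if dy is None else dy
    ny, nx = spec.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    sigma = np.full(spec.shape, float(spec.background))
    for s in spec.shapes:
        inside = s.contains(yy, xx)
        if not inside.any():
            raise ValueError(f"shape {s} is empty on a {spec.shape} grid")
        sigma[inside] = s.sigma
    if spec.smooth_width > 0:
        sigma = ndimage.gaussian_filter(sigma, spec.smooth_width,
                                        mode="nearest")
    field = ScalarField2D(sigma, dx, dy, units="S/m")
    return field, ROIMask.full(spec.shape)


def forward_phase(sigma: ScalarField2D, mask: ROIMask,
                  consts: PhysicsConstants | None = None) -> ScalarField2D:
    """Synthesize a transceive phase map consistent with the conductivity.

    Solves ``div(tau grad(phi)) = 2 omega mu0`` (tau = 1/sigma) on the mask
    interior with phi = 0 on the boundary ring, using harmonic-mean face
    values of tau.  Output is NaN outside the mask.
    """
    consts = consts or PhysicsConstants()
    if sigma.shape != mask.shape:
        raise ValueError("sigma and mask shapes differ")
    sv = sigma.values
    if np.any(sv[mask.inside] <= 0) or not np.isfinite(sv[mask.inside]).all():
        raise ValueError("sigma must be positive and finite on the mask")

    tau = np.full(sigma.shape, np.nan)
    tau[mask.inside] = 1.0 / sv[mask.inside]
    interior = mask.interior()
    boundary = mask.boundary()
    ii, jj = np.nonzero(interior)
    n = ii.size
    if n == 0:
        raise ValueError("mask has no interior voxels")
    index_map = np.full(mask.shape, -1, dtype=int)
    index_map[ii, jj] = np.arange(n)

    dx, dy = sigma.dx, sigma.dy
    rows, cols, vals = [], [], []
    rhs = np.full(n, consts.two_omega_mu0)
    diag = np.zeros(n)
    for di, dj, h in ((0, 1, dx), (0, -1, dx), (1, 0, dy), (-1, 0, dy)):
        ni, nj = ii + di, jj + dj
        # harmonic mean of tau across the face
        tp, tq = tau[ii, jj], tau[ni, nj]
        g = 2.0 * tp * tq / (tp + tq) / h ** 2
        diag -= g
        nb = index_map[ni, nj]
        is_int = nb >= 0
        rows.extend(np.nonzero(is_int)[0])
        cols.extend(nb[is_int])
        vals.extend(g[is_int])
        # boundary neighbors carry phi = 0: nothing moves to the rhs
        outside = ~is_int & ~boundary[ni, nj]
        if outside.any():
            k = np.argmax(outside)
            raise ValueError(f"interior voxel ({ii[k]}, {jj[k]}) touches a "
                             "voxel outside the mask")
    rows.extend(range(n)); cols.extend(range(n)); vals.extend(diag)

    A = csr_matrix((vals, (rows, cols)), shape=(n, n))
    phi_vec = spsolve(A.tocsc(), rhs)
    phi = np.full(mask.shape, np.nan)
    phi[ii, jj] = phi_vec
    phi[boundary] = 0.0
    out = sigma.with_values(phi, units="rad")
    return out


def exact_boundary_tau(sigma: ScalarField2D, mask: ROIMask) -> ScalarField2D:
    """Boundary resistivity 1/sigma on the boundary ring (NaN elsewhere)."""
    out = np.full(sigma.shape, np.nan)
    bnd = mask.boundary()
    out[bnd] = 1.0 / sigma.values[bnd]
    return sigma.with_values(out, units="m/S")


def corrupt_phase(phase: ScalarField2D, spec: CorruptionSpec,
                  mask: ROIMask | None = None) -> ScalarField2D:
    """Apply Gaussian phase noise and defective regions (seeded).

    Noise is added only where the phase is defined (finite) and, if a mask
    is given, inside it.  Defect regions must lie on the grid.
    """
    rng = np.random.default_rng(spec.seed)
    v = phase.values.copy()
    where = np.isfinite(v)
    if mask is not None:
        where &= mask.inside
    if spec.gaussian_sigma > 0:
        noise = rng.normal(0.0, spec.gaussian_sigma, size=v.shape)
        v[where] += noise[where]
    for region in spec.defect_regions:
        region = np.asarray(region, dtype=bool)
        if region.shape != v.shape:
            raise ValueError("defect mask shape differs from the phase grid")
        target = region & where
        if spec.defect_mode == "zero_phase":
            v[target] = 0.0
        else:
            std = (spec.defect_sigma if spec.defect_sigma is not None
                   else spec.defect_noise_scale * spec.gaussian_sigma)
            if std <= 0:
                raise ValueError("heavy_noise defect needs a positive std; "
                                 "set gaussian_sigma or defect_sigma")
            dn = rng.normal(0.0, std, size=v.shape)
            v[target] += dn[target]
    return phase.with_values(v)
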