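"""Deterministic physics reconstructions from B1 transceive phase.

Two routes are implemented:

* the algebraic phase-based estimate ``sigma = lap(phi) / (2 omega mu0)``,
  valid under local homogeneity, and
* the stabilized convection–reaction inverse solver for the resistivity
  ``tau = 1/sigma``:

  .. math::  -c \\nabla^2 \\tau + \\nabla\\phi\\cdot\\nabla\\tau
             + \\tau \\nabla^2\\phi = 2\\omega\\mu_0

  discretized with central differences on the mask interior and assembled
  into one sparse row per interior voxel; references to boundary voxels are
  eliminated into the right-hand side using known boundary ``tau``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.sparse import csr_matrix
from scipy.sparse.linalg import splu, onenormest, gmres

from .fields import (PhysicsConstants, ROIMask, ScalarField2D,
                     gradient_x, gradient_y, laplacian)

#: |tau| below this (m/S) is treated as invalid when inverting tau -> sigma
TAU_GUARD = 1e-6


@dataclass
class SolverConfig:
    """Configuration of the convection–reaction inverse solve.

    c : artificial diffusion coefficient, applied to the discrete Laplacian
        of tau exactly as written (spacing in meters).
    boundary_strategy : "supplied" uses the caller's boundary tau;
        "algebraic_estimate" derives it from the algebraic reconstruction.
    linear_solver : "sparse_direct" (LU) or "iterative" (GMRES).
    tolerance : relative tolerance of the iterative solver.
    """

    c: float = 0.02
    boundary_strategy: str = "supplied"
    linear_solver: str = "sparse_direct"
    tolerance: float = 1e-10

    def __post_init__(self):
        if self.c < 0:
            raise ValueError("diffusion coefficient c must be >= 0")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.boundary_strategy not in ("supplied", "algebraic_estimate"):
            raise ValueError(f"unknown boundary strategy "
                             f"{self.boundary_strategy!r}")
        if self.linear_solver not in ("sparse_direct", "iterative"):
            raise ValueError(f"unknown linear solver {self.linear_solver!r}")


@dataclass
class LinearSystem:
    """Sparse global system A x = b over the interior voxels.

    ``index_map`` is a 2-D int array, -1 outside the interior, otherwise the
    row index of that voxel; ``interior_ij`` lists (row, col) per system row.
    """

    matrix: csr_matrix
    rhs: np.ndarray
    index_map: np.ndarray
    interior_ij: np.ndarray


def algebraic_sigma(phase: ScalarField2D, mask: ROIMask,
                    consts: PhysicsConstants | None = None) -> ScalarField2D:
    """Algebraic phase-based EPT: sigma = lap(phi) / (2 omega mu0), S/m.

    Exact for locally homogeneous conductivity; NaN where the Laplacian
    stencil is incomplete.
    """
    consts = consts or PhysicsConstants()
    lap = laplacian(phase, mask)
    sigma = lap.values / consts.two_omega_mu0
    out = phase.with_values(sigma, units="S/m")
    out.meta["n_valid"] = int(np.isfinite(sigma).sum())
    return out


_OFFSETS = ((0, 1), (0, -1), (1, 0), (-1, 0))  # E, W, N(+y), S(-y)


def assemble_system(phase: ScalarField2D, mask: ROIMask, cfg: SolverConfig,
                    boundary_tau: ScalarField2D,
                    consts: PhysicsConstants | None = None) -> LinearSystem:
    """Assemble the sparse convection–reaction system over the interior.

    Row for interior voxel (i, j), with tau_E = tau[i, j+1] etc.:

        -c [(tau_E - 2 tau + tau_W)/dx^2 + (tau_N - 2 tau + tau_S)/dy^2]
        + phi_x (tau_E - tau_W)/(2 dx) + phi_y (tau_N - tau_S)/(2 dy)
        + tau lap(phi)  =  2 omega mu0

    Boundary-voxel references are moved to the rhs with ``boundary_tau``.
    """
    consts = consts or PhysicsConstants()
    if phase.shape != mask.shape:
        raise ValueError("phase and mask shapes differ")
    interior = mask.interior()
    boundary = mask.boundary()
    if not interior.any():
        raise ValueError("mask has no interior voxels")

    phix = gradient_x(phase, mask).values
    phiy = gradient_y(phase, mask).values
    lap = laplacian(phase, mask).values
    if not (np.isfinite(phix[interior]).all()
            and np.isfinite(lap[interior]).all()):
        raise ValueError("phase contains NaN inside the interior stencil")

    dx, dy, c = phase.dx, phase.dy, cfg.c
    ii, jj = np.nonzero(interior)
    n = ii.size
    index_map = np.full(mask.shape, -1, dtype=int)
    index_map[ii, jj] = np.arange(n)

    rows, cols, vals = [], [], []
    rhs = np.full(n, consts.two_omega_mu0)

    diag = 2.0 * c / dx ** 2 + 2.0 * c / dy ** 2 + lap[ii, jj]
    rows.extend(range(n)); cols.extend(range(n)); vals.extend(diag)

    btau = boundary_tau.values if boundary_tau is not None else None
    for di, dj in _OFFSETS:
        if dj != 0:  # x-neighbor
            coef = -c / dx ** 2 + dj * phix[ii, jj] / (2.0 * dx)
        else:        # y-neighbor
            coef = -c / dy ** 2 + di * phiy[ii, jj] / (2.0 * dy)
        ni, nj = ii + di, jj + dj
        nb_row = index_map[ni, nj]
        is_int = nb_row >= 0
        is_bnd = boundary[ni, nj]
        bad = ~is_int & ~is_bnd
        if bad.any():
            k = np.argmax(bad)
            raise ValueError(
                f"stencil of interior voxel ({ii[k]}, {jj[k]}) touches voxel "
                f"({ni[k]}, {nj[k]}) which is neither interior nor boundary")
        rows.extend(np.nonzero(is_int)[0])
        cols.extend(nb_row[is_int])
        vals.extend(coef[is_int])
        if is_bnd.any():
            if btau is None:
                raise ValueError("boundary tau required but not supplied")
            tb = btau[ni[is_bnd], nj[is_bnd]]
            if not np.isfinite(tb).all():
                raise ValueError("boundary tau is NaN on a referenced voxel")
            rhs[np.nonzero(is_bnd)[0]] -= coef[is_bnd] * tb

    A = csr_matrix((vals, (rows, cols)), shape=(n, n))
    return LinearSystem(A, rhs, index_map, np.column_stack([ii, jj]))


def default_boundary_tau(phase: ScalarField2D, mask: ROIMask,
                         consts: PhysicsConstants | None = None
                         ) -> ScalarField2D:
    """Boundary tau estimate when the true value is unavailable.

    Inverts the algebraic reconstruction, median-filters it over 3x3
    neighborhoods (NaN-aware), and takes the nearest finite value for each
    boundary voxel.
    """
    consts = consts or PhysicsConstants()
    sig = algebraic_sigma(phase, mask, consts).values
    with np.errstate(divide="ignore", invalid="ignore"):
        tau = np.where(np.abs(sig) > TAU_GUARD, 1.0 / sig, np.nan)
    # NaN-aware 3x3 median
    med = ndimage.generic_filter(tau, _nanmedian_or_nan, size=3,
                                 mode="constant", cval=np.nan)
    filled = np.where(np.isfinite(med), med, tau)
    out = np.full(mask.shape, np.nan)
    bnd = mask.boundary()
    finite = np.isfinite(filled)
    if not finite.any():
        raise ValueError("cannot estimate boundary tau: no finite values")
    # nearest finite value for boundary voxels lacking one
    ind = ndimage.distance_transform_edt(~finite, return_distances=False,
                                         return_indices=True)
    nearest = filled[tuple(ind)]
    out[bnd] = np.where(finite[bnd], filled[bnd], nearest[bnd])
    return phase.with_values(out, units="m/S")


def _nanmedian_or_nan(window):
    w = window[np.isfinite(window)]
    return np.median(w) if w.size else np.nan


def solve_sigma_pde(phase: ScalarField2D, mask: ROIMask,
                    cfg: SolverConfig | None = None,
                    boundary_tau: ScalarField2D | None = None,
                    consts: PhysicsConstants | None = None) -> ScalarField2D:
    """Solve the stabilized convection–reaction system for sigma (S/m).

    The output carries the solved interior values, the supplied boundary
    values (as 1/tau), and NaN outside the mask.  Diagnostics (condition
    estimate, invalid-voxel count) land in ``.meta``.
    """
    cfg = cfg or SolverConfig()
    consts = consts or PhysicsConstants()
    if boundary_tau is None or cfg.boundary_strategy == "algebraic_estimate":
        boundary_tau = default_boundary_tau(phase, mask, consts)

    system = assemble_system(phase, mask, cfg, boundary_tau, consts)
    A, b = system.matrix.tocsc(), system.rhs

    diag = A.diagonal()
    if np.abs(A).sum() == 0 or (diag == 0).all() and A.nnz == A.shape[0]:
        raise np.linalg.LinAlgError("assembled system is singular "
                                    "(zero matrix)")
    try:
        if cfg.linear_solver == "sparse_direct":
            lu = splu(A)
            tau_vec = lu.solve(b)
            cond = _condition_estimate(A, lu)
        else:
            tau_vec, info = gmres(A, b, rtol=cfg.tolerance, maxiter=5000)
            if info != 0:
                raise np.linalg.LinAlgError(
                    f"GMRES failed to converge (info={info})")
            cond = float("nan")
    except RuntimeError as exc:  # pragma: no cover - splu failure path
        raise np.linalg.LinAlgError(f"sparse LU failed: {exc}") from exc
    if not np.isfinite(tau_vec).all():
        raise np.linalg.LinAlgError("singular system: non-finite solution")

    tau = np.full(mask.shape, np.nan)
    ii, jj = system.interior_ij.T
    tau[ii, jj] = tau_vec
    bnd = mask.boundary()
    tau[bnd] = boundary_tau.values[bnd]

    with np.errstate(divide="ignore", invalid="ignore"):
        sigma = np.where(np.abs(tau) > TAU_GUARD, 1.0 / tau, np.nan)
    invalid = mask.inside & (~np.isfinite(sigma) | (tau <= 0))
    sigma[invalid] = np.nan

    out = phase.with_values(sigma, units="S/m")
    out.meta["n_invalid"] = int(invalid.sum())
    out.meta["condition_estimate"] = cond
    return out


def _condition_estimate(A, lu) -> float:
    """1-norm condition estimate via the LU factors."""
    try:
        inv_norm = onenormest(_InverseOperator(lu, A.shape[0]))
        return float(onenormest(A) * inv_norm)
    except Exception:  # pragma: no cover
        return float("nan")


class _InverseOperator:
    """Minimal LinearOperator-like wrapper around an splu factorization."""

    def __init__(self, lu, n):
        self.lu = lu
        self.shape = (n, n)
        self.dtype = np.dtype(float)

    def matvec(self, x):
        return self.lu.solve(x)

    def rmatvec(self, x):
        return self.lu.solve(x, trans="T")

    def matmat(self, X):
        return self.lu.solve(X)
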