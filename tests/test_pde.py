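"""Algebraic EPT and the convection-reaction inverse solver."""

import numpy as np
import pytest

from mrept import (PhysicsConstants, ROIMask, ScalarField2D, SolverConfig,
                   algebraic_sigma, assemble_system, default_boundary_tau,
                   exact_boundary_tau, forward_phase, make_phantom, rel_l2,
                   solve_sigma_pde)
from mrept.phantom import Disk, PhantomSpec

from conftest import random_mask


def dense_assembly_oracle(phase, mask, c, boundary_tau, consts):
    """Loop-built dense matrix and rhs, independent of the sparse path."""
    v, dx, dy = phase.values, phase.dx, phase.dy
    inside = mask.inside
    interior = mask.interior()
    boundary = mask.boundary()
    ii, jj = np.nonzero(interior)
    n = ii.size
    idx = {(i, j): k for k, (i, j) in enumerate(zip(ii, jj))}
    A = np.zeros((n, n))
    b = np.full(n, consts.two_omega_mu0)
    for k, (i, j) in enumerate(zip(ii, jj)):
        px = (v[i, j + 1] - v[i, j - 1]) / (2 * dx)
        py = (v[i + 1, j] - v[i - 1, j]) / (2 * dy)
        lap = ((v[i, j + 1] - 2 * v[i, j] + v[i, j - 1]) / dx ** 2
               + (v[i + 1, j] - 2 * v[i, j] + v[i - 1, j]) / dy ** 2)
        A[k, k] = 2 * c / dx ** 2 + 2 * c / dy ** 2 + lap
        for di, dj, coef in (
                (0, 1, -c / dx ** 2 + px / (2 * dx)),
                (0, -1, -c / dx ** 2 - px / (2 * dx)),
                (1, 0, -c / dy ** 2 + py / (2 * dy)),
                (-1, 0, -c / dy ** 2 - py / (2 * dy))):
            ni, nj = i + di, j + dj
            if interior[ni, nj]:
                A[k, idx[(ni, nj)]] = coef
            elif boundary[ni, nj]:
                b[k] -= coef * boundary_tau.values[ni, nj]
            else:
                raise AssertionError("oracle hit an invalid stencil")
    return A, b


def smooth_phase(shape, rng, dx=1e-3):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]].astype(float)
    coef = rng.normal(size=5)
    v = (0.1 * coef[0] * np.sin(xx / 3) + 0.1 * coef[1] * np.cos(yy / 2.5)
         + 0.01 * coef[2] * xx * yy / 10 + 0.05 * coef[3] * xx / 5
         + 0.05 * coef[4] * yy / 5)
    return ScalarField2D(v, dx=dx, dy=dx, units="rad")


class TestAssembly:
    @pytest.mark.parametrize("c", [0.0, 0.005, 0.02])
    def test_sparse_equals_dense_oracle_on_random_masks(self, c, consts):
        rng = np.random.default_rng(17)
        for trial in range(6):
            shape = rng.integers(5, 9), rng.integers(5, 9)
            mask = random_mask(tuple(shape), rng, p_inside=0.9)
            phase = smooth_phase(tuple(shape), rng)
            btau = ScalarField2D(
                np.abs(rng.normal(2.0, 0.3, size=tuple(shape))),
                dx=phase.dx, dy=phase.dy, units="m/S")
            try:
                sys_ = assemble_system(phase, mask, SolverConfig(c=c),
                                       btau, consts)
            except ValueError:
                # disconnected interior touching outside voxels: the
                # oracle would reject it too
                continue
            A_ref, b_ref = dense_assembly_oracle(phase, mask, c, btau,
                                                 consts)
            np.testing.assert_array_equal(sys_.matrix.toarray(), A_ref)
            np.testing.assert_array_equal(sys_.rhs, b_ref)

    def test_constant_phase_reduces_to_poisson(self, consts):
        # convection and reaction vanish; matrix = -c * 5-point Laplacian
        shape = (6, 6)
        mask = ROIMask.full(shape)
        phase = ScalarField2D(np.full(shape, 0.3), dx=2.0, dy=2.0)
        btau = ScalarField2D(np.ones(shape), dx=2.0, dy=2.0)
        c = 0.7
        sys_ = assemble_system(phase, mask, SolverConfig(c=c), btau, consts)
        n = sys_.matrix.shape[0]
        A = sys_.matrix.toarray()
        np.testing.assert_allclose(np.diag(A), 4 * c / 4.0)
        offdiag = A - np.diag(np.diag(A))
        assert set(np.round(offdiag[offdiag != 0], 12)) == {-c / 4.0}

    def test_constant_phase_c_zero_is_singular(self, consts):
        shape = (6, 6)
        mask = ROIMask.full(shape)
        phase = ScalarField2D(np.full(shape, 0.3))
        btau = ScalarField2D(np.ones(shape))
        with pytest.raises(np.linalg.LinAlgError):
            solve_sigma_pde(phase, mask, SolverConfig(c=0.0), btau, consts)

    def test_nan_phase_in_interior_raises(self, consts):
        shape = (6, 6)
        mask = ROIMask.full(shape)
        v = np.random.default_rng(0).normal(size=shape)
        v[3, 3] = np.nan
        phase = ScalarField2D(v)
        btau = ScalarField2D(np.ones(shape))
        with pytest.raises(ValueError):
            assemble_system(phase, mask, SolverConfig(), btau, consts)


class TestAlgebraicSigma:
    def test_recovers_constant_conductivity_from_poisson_phase(self, consts):
        # forward phase for uniform sigma solves lap(phi) = 2 w mu0 sigma0
        spec = PhantomSpec(shape=(24, 24), background=0.5, shapes=[],
                           smooth_width=0.0)
        sigma, mask = make_phantom(spec)
        phase = forward_phase(sigma, mask, consts)
        rec = algebraic_sigma(phase, mask, consts)
        interior2 = ROIMask(mask.interior()).interior()  # full lap stencil
        np.testing.assert_allclose(rec.values[interior2], 0.5, rtol=1e-9)

    def test_linear_phase_gives_zero(self, consts):
        yy, xx = np.mgrid[0:8, 0:8].astype(float)
        phase = ScalarField2D(0.01 * xx, dx=1e-3, dy=1e-3, units="rad")
        mask = ROIMask.full((8, 8))
        rec = algebraic_sigma(phase, mask, consts)
        sel = np.isfinite(rec.values)
        np.testing.assert_allclose(rec.values[sel], 0.0, atol=1e-12)


class TestSolve:
    def test_homogeneous_round_trip(self, consts):
        spec = PhantomSpec(shape=(32, 32), background=0.5, shapes=[],
                           smooth_width=0.0)
        sigma, mask = make_phantom(spec)
        phase = forward_phase(sigma, mask, consts)
        btau = exact_boundary_tau(sigma, mask)
        rec = solve_sigma_pde(phase, mask, SolverConfig(c=1e-4), btau,
                              consts)
        interior = mask.interior()
        np.testing.assert_allclose(rec.values[interior], 0.5, rtol=1e-3)

    def test_two_compartment_round_trip(self, consts):
        from scipy import ndimage
        spec = PhantomSpec(shape=(48, 48), background=0.3,
                           shapes=[Disk(sigma=1.8, cy=24, cx=24, r=11)])
        sigma, mask = make_phantom(spec)
        phase = forward_phase(sigma, mask, consts)
        btau = exact_boundary_tau(sigma, mask)
        rec = solve_sigma_pde(phase, mask, SolverConfig(c=1e-4), btau,
                              consts)
        gy, gx = np.gradient(sigma.values)
        band = ndimage.binary_dilation(np.abs(gy) + np.abs(gx) > 1e-3)
        sel = ROIMask(mask.interior() & ~band)
        assert rel_l2(sigma, rec, sel) < 0.05

    def test_solution_is_initial_guess_free(self, consts):
        # direct linear solve: calling twice yields identical images
        spec = PhantomSpec(shape=(20, 20), background=0.6, shapes=[],
                           smooth_width=0.0)
        sigma, mask = make_phantom(spec)
        phase = forward_phase(sigma, mask, consts)
        btau = exact_boundary_tau(sigma, mask)
        a = solve_sigma_pde(phase, mask, SolverConfig(c=1e-3), btau, consts)
        b = solve_sigma_pde(phase, mask, SolverConfig(c=1e-3), btau, consts)
        np.testing.assert_array_equal(a.values, b.values)

    def test_diagnostics_present(self, consts):
        spec = PhantomSpec(shape=(16, 16), background=0.4, shapes=[],
                           smooth_width=0.0)
        sigma, mask = make_phantom(spec)
        phase = forward_phase(sigma, mask, consts)
        btau = exact_boundary_tau(sigma, mask)
        rec = solve_sigma_pde(phase, mask, SolverConfig(c=1e-4), btau,
                              consts)
        assert rec.meta["condition_estimate"] > 1.0
        assert rec.meta["n_invalid"] == 0

    def test_increasing_c_smooths_the_solution(self, consts):
        # total variation non-increasing in c on a fixed noisy phantom
        from mrept import CorruptionSpec, corrupt_phase
        spec = PhantomSpec(shape=(48, 48), background=0.4,
                           shapes=[Disk(sigma=1.5, cy=24, cx=24, r=10)])
        sigma, mask = make_phantom(spec)
        phase = corrupt_phase(forward_phase(sigma, mask, consts),
                              CorruptionSpec(gaussian_sigma=0.002, seed=3))
        btau = exact_boundary_tau(sigma, mask)
        tvs = []
        for c in (0.005, 0.02, 0.1):
            rec = solve_sigma_pde(phase, mask, SolverConfig(c=c), btau,
                                  consts).values
            rec = np.nan_to_num(rec, nan=0.0)
            tv = np.abs(np.diff(rec, axis=0)).sum() + \
                np.abs(np.diff(rec, axis=1)).sum()
            tvs.append(tv)
        assert tvs[0] >= tvs[1] >= tvs[2]

    def test_default_boundary_tau_is_finite_on_boundary(self, consts):
        spec = PhantomSpec(shape=(24, 24), background=0.5, shapes=[],
                           smooth_width=0.0)
        sigma, mask = make_phantom(spec)
        phase = forward_phase(sigma, mask, consts)
        btau = default_boundary_tau(phase, mask, consts)
        assert np.isfinite(btau.values[mask.boundary()]).all()
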