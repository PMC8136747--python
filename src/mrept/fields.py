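"""Grid containers and finite-difference primitives for phase-based EPT.

Coordinate convention (used everywhere in this package): arrays are indexed
``[row, col]`` with row = y and col = x, 0-based.  ``gradient_x`` therefore
differentiates along axis 1 with spacing ``dx``, ``gradient_y`` along axis 0
with spacing ``dy``.  All spacings are SI meters so that conductivities come
out in S/m without rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage

#: default in-plane voxel size: 240 mm field of view over a 128 matrix
DEFAULT_SPACING = 0.240 / 128  # 1.875e-3 m

#: magnetic permeability of free space, N/A^2
MU0 = 4.0e-7 * np.pi

_CROSS = ndimage.generate_binary_structure(2, 1)  # 4-connectivity


def _as_float_2d(a) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim != 2:
        raise ValueError(f"expected a 2-D array, got shape {a.shape}")
    return a


@dataclass
class ScalarField2D:
    """A real-valued 2-D map on a regular grid.

    Parameters
    ----------
    values : 2-D array, row = y, col = x.  NaN marks voxels where the
        quantity is undefined (outside the ROI or stencil-incomplete).
    dx, dy : grid spacing in meters (must be positive).
    units : free-form tag, e.g. ``"rad"``, ``"S/m"``, ``"m/S"``,
        ``"rad/m"``, ``"rad/m^2"``.
    meta : diagnostics accumulated by operations (NaN counts etc.).
    """

    values: np.ndarray
    dx: float = DEFAULT_SPACING
    dy: float = DEFAULT_SPACING
    units: str = ""
    meta: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        self.values = _as_float_2d(self.values)
        if not (self.dx > 0 and self.dy > 0):
            raise ValueError("grid spacings dx, dy must be positive")

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def with_values(self, values, units: str | None = None) -> "ScalarField2D":
        """New field on the same grid, optionally retagging units."""
        return ScalarField2D(np.asarray(values, dtype=float), self.dx, self.dy,
                             self.units if units is None else units)

    def copy(self) -> "ScalarField2D":
        return ScalarField2D(self.values.copy(), self.dx, self.dy, self.units,
                             dict(self.meta))


@dataclass
class ROIMask:
    """Boolean region-of-interest mask on the same grid as the fields.

    ``interior`` voxels have all four edge-neighbors inside the mask;
    ``boundary`` voxels are inside but touch the outside.  The two sets
    partition the mask.
    """

    inside: np.ndarray

    def __post_init__(self):
        self.inside = np.asarray(self.inside, dtype=bool)
        if self.inside.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def shape(self) -> tuple:
        return self.inside.shape

    def interior(self) -> np.ndarray:
        return ndimage.binary_erosion(self.inside, structure=_CROSS,
                                      border_value=0)

    def boundary(self) -> np.ndarray:
        return self.inside & ~self.interior()

    @classmethod
    def full(cls, shape) -> "ROIMask":
        return cls(np.ones(shape, dtype=bool))


@dataclass
class PhysicsConstants:
    """Angular Larmor frequency and vacuum permeability.

    Defaults correspond to a 3 T scanner (f0 = 128 MHz).
    """

    omega: float = 2.0 * np.pi * 128e6  # rad/s
    mu0: float = MU0                    # N/A^2

    def __post_init__(self):
        if self.omega <= 0 or self.mu0 <= 0:
            raise ValueError("omega and mu0 must be positive")

    @property
    def two_omega_mu0(self) -> float:
        """The source constant 2*omega*mu0 of the phase-based EPT relation."""
        return 2.0 * self.omega * self.mu0


@dataclass
class EchoStack:
    """Complex multi-echo MR signals on a shared grid."""

    signals: list          # list of complex 2-D arrays, one per echo
    echo_numbers: list     # 1-based echo indices, parallel to ``signals``
    dx: float = DEFAULT_SPACING
    dy: float = DEFAULT_SPACING

    def __post_init__(self):
        if len(self.signals) == 0:
            raise ValueError("echo stack is empty")
        if len(self.signals) != len(self.echo_numbers):
            raise ValueError("signals and echo_numbers differ in length")
        self.signals = [np.asarray(s, dtype=complex) for s in self.signals]
        shape = self.signals[0].shape
        if any(s.shape != shape for s in self.signals):
            raise ValueError("all echoes must share one shape")


def combine_echo_phase(stack: EchoStack, echoes=(1, 3, 5)) -> ScalarField2D:
    """Magnitude-weighted average of per-echo phases.

    The weight of echo k at a voxel is ``|S_k|^2 / sum_j |S_j|^2`` over the
    echoes selected (odd echoes by default, which avoids the alternating
    background phase of consecutive refocusing pulses).  Weights sum to 1 at
    every voxel with nonzero total magnitude; voxels where every selected
    echo has zero magnitude get NaN and are counted in ``meta['n_undefined']``.

    Phase unwrapping is *not* performed: inputs are assumed unwrapped.
    """
    sel = [i for i, k in enumerate(stack.echo_numbers) if k in set(echoes)]
    if not sel:
        raise ValueError(f"none of the requested echoes {echoes} are present "
                         f"(stack has {stack.echo_numbers})")
    mags2 = np.stack([np.abs(stack.signals[i]) ** 2 for i in sel])
    phases = np.stack([np.angle(stack.signals[i]) for i in sel])
    denom = mags2.sum(axis=0)
    ok = denom > 0
    combined = np.full(denom.shape, np.nan)
    weights = np.where(ok, mags2 / np.where(ok, denom, 1.0), np.nan)
    combined[ok] = (weights * phases).sum(axis=0)[ok]
    out = ScalarField2D(combined, stack.dx, stack.dy, units="rad")
    out.meta["n_undefined"] = int((~ok).sum())
    return out


def _shift(a: np.ndarray, di: int, dj: int, fill):
    """out[i, j] = a[i + di, j + dj], padded with ``fill``."""
    out = np.full(a.shape, fill, dtype=a.dtype)
    ni, nj = a.shape
    src_i = slice(max(di, 0), ni + min(di, 0))
    src_j = slice(max(dj, 0), nj + min(dj, 0))
    dst_i = slice(max(-di, 0), ni + min(-di, 0))
    dst_j = slice(max(-dj, 0), nj + min(-dj, 0))
    out[dst_i, dst_j] = a[src_i, src_j]
    return out


def _check_shapes(f: ScalarField2D, mask: ROIMask):
    if f.shape != mask.shape:
        raise ValueError(f"field shape {f.shape} != mask shape {mask.shape}")


def _deriv_units(units: str, suffix: str) -> str:
    return f"{units}{suffix}" if units else ""


def gradient_x(f: ScalarField2D, mask: ROIMask,
               edge: str = "strict") -> ScalarField2D:
    """Central-difference d/dx; see :func:`gradient_y` for conventions.

    ``edge="strict"`` (default): defined only where both x-neighbors are in
    the mask, NaN elsewhere.  ``edge="one_sided"``: mask-edge voxels fall
    back to a 3-point one-sided second-order stencil when two consecutive
    in-mask neighbors exist on one side.
    """
    return _gradient(f, mask, axis=1, edge=edge)


def gradient_y(f: ScalarField2D, mask: ROIMask,
               edge: str = "strict") -> ScalarField2D:
    return _gradient(f, mask, axis=0, edge=edge)


def _gradient(f: ScalarField2D, mask: ROIMask, axis: int,
              edge: str) -> ScalarField2D:
    _check_shapes(f, mask)
    m = mask.inside
    v = f.values
    h = f.dx if axis == 1 else f.dy
    d = (0, 1) if axis == 1 else (1, 0)

    fwd = _shift(v, *d, np.nan)
    bwd = _shift(v, -d[0], -d[1], np.nan)
    m_fwd = _shift(m, *d, False)
    m_bwd = _shift(m, -d[0], -d[1], False)

    out = np.full(v.shape, np.nan)
    central = m & m_fwd & m_bwd
    out[central] = (fwd[central] - bwd[central]) / (2.0 * h)

    if edge == "one_sided":
        fwd2 = _shift(v, 2 * d[0], 2 * d[1], np.nan)
        bwd2 = _shift(v, -2 * d[0], -2 * d[1], np.nan)
        m_fwd2 = _shift(m, 2 * d[0], 2 * d[1], False)
        m_bwd2 = _shift(m, -2 * d[0], -2 * d[1], False)
        # 2nd-order one-sided: f' = (-3 f0 + 4 f1 - f2) / (2 h)
        left = m & ~m_bwd & m_fwd & m_fwd2
        out[left] = (-3 * v[left] + 4 * fwd[left] - fwd2[left]) / (2.0 * h)
        right = m & ~m_fwd & m_bwd & m_bwd2
        out[right] = (3 * v[right] - 4 * bwd[right] + bwd2[right]) / (2.0 * h)
    elif edge != "strict":
        raise ValueError(f"unknown edge mode {edge!r}")

    res = f.with_values(out, units=_deriv_units(f.units, "/m"))
    res.meta["n_valid"] = int(np.isfinite(out).sum())
    return res


def laplacian(f: ScalarField2D, mask: ROIMask,
              edge: str = "strict") -> ScalarField2D:
    """5-point Laplacian on the mask.

    ``edge="strict"``: NaN wherever the full 5-point stencil is not inside
    the mask.  ``edge="one_sided"``: along an axis whose central 3-point
    second difference is incomplete, shift the 3-point stencil into the mask
    (first-order accurate at the edge).
    """
    _check_shapes(f, mask)
    m = mask.inside
    v = f.values
    out = np.zeros(v.shape)
    valid = m.copy()
    for axis, h in ((1, f.dx), (0, f.dy)):
        d2, ok = _second_diff(v, m, axis, h, edge)
        out += d2
        valid &= ok
    out = np.where(valid, out, np.nan)
    res = f.with_values(out, units=_deriv_units(f.units, "/m^2"))
    res.meta["n_valid"] = int(valid.sum())
    return res


def _second_diff(v, m, axis, h, edge):
    d = (0, 1) if axis == 1 else (1, 0)
    fwd = _shift(v, *d, np.nan)
    bwd = _shift(v, -d[0], -d[1], np.nan)
    m_fwd = _shift(m, *d, False)
    m_bwd = _shift(m, -d[0], -d[1], False)
    out = np.zeros(v.shape)
    central = m & m_fwd & m_bwd
    ok = central.copy()
    out[central] = (fwd[central] - 2 * v[central] + bwd[central]) / h ** 2
    if edge == "one_sided":
        fwd2 = _shift(v, 2 * d[0], 2 * d[1], np.nan)
        fwd3 = _shift(v, 3 * d[0], 3 * d[1], np.nan)
        bwd2 = _shift(v, -2 * d[0], -2 * d[1], np.nan)
        bwd3 = _shift(v, -3 * d[0], -3 * d[1], np.nan)
        m_fwd2 = _shift(m, 2 * d[0], 2 * d[1], False)
        m_fwd3 = _shift(m, 3 * d[0], 3 * d[1], False)
        m_bwd2 = _shift(m, -2 * d[0], -2 * d[1], False)
        m_bwd3 = _shift(m, -3 * d[0], -3 * d[1], False)
        # 2nd-order one-sided: f'' = (2 f0 - 5 f1 + 4 f2 - f3) / h^2
        left = m & ~m_bwd & m_fwd & m_fwd2 & m_fwd3
        out[left] = (2 * v[left] - 5 * fwd[left] + 4 * fwd2[left]
                     - fwd3[left]) / h ** 2
        ok |= left
        right = m & ~m_fwd & m_bwd & m_bwd2 & m_bwd3
        out[right] = (2 * v[right] - 5 * bwd[right] + 4 * bwd2[right]
                      - bwd3[right]) / h ** 2
        ok |= right
    elif edge != "strict":
        raise ValueError(f"unknown edge mode {edge!r}")
    return out, ok


def phase_derivatives(phase: ScalarField2D, mask: ROIMask,
                      edge: str = "one_sided"):
    """The derivative family (d/dx, d/dy, Laplacian) used as network features.

    Defaults to edge-aware stencils so the family is finite on the whole
    mask wherever enough in-mask support exists (three consecutive voxels
    per axis for the gradient, four for the shifted second difference).
    """
    return (gradient_x(phase, mask, edge=edge),
            gradient_y(phase, mask, edge=edge),
            laplacian(phase, mask, edge=edge))
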