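"""Readers and writers for MATLAB .mat arrays and NIfTI volumes.

.mat files round-trip 2-D double arrays bit-exactly (MATLAB v5 format via
scipy.io).  NIfTI spacing follows the format's convention of millimeters
in the header and is converted to SI meters on load.
"""

from __future__ import annotations

import os

import numpy as np
import scipy.io

from .fields import DEFAULT_SPACING, ROIMask, ScalarField2D


def save_mat(path, **arrays):
    scipy.io.savemat(path, {k: np.asarray(v) for k, v in arrays.items()})


def load_mat(path, var: str | None = None) -> np.ndarray:
    data = scipy.io.loadmat(path)
    keys = [k for k in data if not k.startswith("__")]
    if var is None:
        if len(keys) != 1:
            raise ValueError(f"{path} holds variables {keys}; pass var=...")
        var = keys[0]
    if var not in data:
        raise KeyError(f"variable {var!r} not in {path} (has {keys})")
    return np.asarray(data[var])


def load_field(path, var: str | None = None, dx: float = DEFAULT_SPACING,
               dy: float | None = None, units: str = "") -> ScalarField2D:
    """Load a 2-D field; format chosen by extension (.mat, .nii, .nii.gz).

    For .mat the spacing must be supplied (default: the 240 mm / 128
    acquisition voxel); for NIfTI it is read from the header (mm -> m).
    """
    ext = _ext(path)
    if ext == ".mat":
        values = np.squeeze(load_mat(path, var)).astype(float)
        return ScalarField2D(values, dx, dx if dy is None else dy, units)
    elif ext in (".nii", ".nii.gz"):
        import nibabel as nib
        img = nib.load(path)
        values = np.squeeze(np.asarray(img.dataobj, dtype=float))
        if values.ndim != 2:
            raise ValueError(f"{path}: expected a single 2-D slice, got "
                             f"shape {values.shape}")
        zooms = img.header.get_zooms()[:2]
        return ScalarField2D(values, float(zooms[0]) * 1e-3,
                             float(zooms[1]) * 1e-3, units)
    raise ValueError(f"unsupported extension on {path}")


def save_field(field: ScalarField2D, path, var: str = "data"):
    ext = _ext(path)
    if ext == ".mat":
        save_mat(path, **{var: field.values})
    elif ext in (".nii", ".nii.gz"):
        import nibabel as nib
        affine = np.diag([field.dx * 1e3, field.dy * 1e3, 1.0, 1.0])
        img = nib.Nifti1Image(field.values[:, :, None], affine)
        img.header.set_zooms((field.dx * 1e3, field.dy * 1e3, 1.0))
        nib.save(img, path)
    else:
        raise ValueError(f"unsupported extension on {path}")


def load_mask(path, var: str | None = None) -> ROIMask:
    f = load_field(path, var)
    return ROIMask(f.values > 0.5)


def _ext(path) -> str:
    path = os.fspath(path)
    if path.endswith(".nii.gz"):
        return ".nii.gz"
    return os.path.splitext(path)[1].lower()
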