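"""Image-quality metrics and ROI statistics for conductivity maps.

All metrics are masked: only ROI voxels enter, and voxels that are NaN in
either image are excluded (their count is reported).  PSNR uses the peak
of the *reference* image on the mask as the dynamic range — conductivity
has no canonical 8-bit-style range.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .fields import ROIMask, ScalarField2D


def _masked_pair(x: ScalarField2D, y: ScalarField2D, mask: ROIMask):
    if x.shape != y.shape or x.shape != mask.shape:
        raise ValueError("shape mismatch between images and mask")
    if not mask.inside.any():
        raise ValueError("empty mask")
    sel = mask.inside & np.isfinite(x.values) & np.isfinite(y.values)
    n_excluded = int(mask.inside.sum() - sel.sum())
    if not sel.any():
        raise ValueError("no valid (finite) voxels under the mask")
    return x.values[sel], y.values[sel], n_excluded


def psnr(x: ScalarField2D, y: ScalarField2D, mask: ROIMask) -> float:
    """Peak signal-to-noise ratio in dB, 10*log10(max(x)^2 / MSE).

    Returns +inf when the images agree exactly on the mask.
    """
    xv, yv, _ = _masked_pair(x, y, mask)
    mse = float(np.mean((xv - yv) ** 2))
    if mse == 0.0:
        return float("inf")
    peak = float(np.max(xv))
    return float(10.0 * np.log10(peak ** 2 / mse))


def rel_l2(x: ScalarField2D, y: ScalarField2D, mask: ROIMask) -> float:
    """Relative L2 error ||x - y||_2 / ||x||_2 over the masked voxels."""
    xv, yv, _ = _masked_pair(x, y, mask)
    denom = float(np.linalg.norm(xv))
    if denom == 0.0:
        raise ValueError("reference image is identically zero on the mask")
    return float(np.linalg.norm(xv - yv) / denom)


def roi_stats(sigma: ScalarField2D, rois: dict) -> dict:
    """Per-ROI mean and sample std, ``{name: (mean, std)}``.

    ``rois`` maps names to boolean masks (or ROIMask); empty or all-NaN
    ROIs raise with the offending name.
    """
    out = {}
    for name, roi in rois.items():
        inside = roi.inside if isinstance(roi, ROIMask) else \
            np.asarray(roi, dtype=bool)
        if inside.shape != sigma.shape:
            raise ValueError(f"ROI {name!r} shape mismatch")
        vals = sigma.values[inside]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError(f"ROI {name!r} is empty")
        std = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
        out[name] = (float(np.mean(vals)), std)
    return out


@dataclass
class EvalReport:
    """Metrics of one reconstruction route under one condition."""

    condition: str
    method: str
    psnr: float
    rel_l2: float
    roi_stats: dict = dc_field(default_factory=dict)
    provenance: dict = dc_field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"condition": self.condition, "method": self.method,
                "psnr": self.psnr, "rel_l2": self.rel_l2,
                "roi_stats": {k: list(v) for k, v in self.roi_stats.items()},
                "provenance": self.provenance}
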