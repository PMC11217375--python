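"""Deformation-field quality metrics.

Accuracy: target registration error (TRE) at landmarks and mean endpoint
error against a dense ground truth.  Physical plausibility: statistics of
the Jacobian determinant (SDLogJac, mean |Jac - 1|), mask overlap (Dice),
and the mean curl magnitude inside a region.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import binary_erosion

from .fields import VectorField, curl, jacobian_determinant, _sample_trilinear
from .synthetic import LandmarkSet

__all__ = [
    "tre",
    "endpoint_error",
    "sdlogjac",
    "jac_deviation",
    "dsc",
    "mean_curl_magnitude",
    "FoldingError",
]


class FoldingError(ValueError):
    """Raised when the Jacobian determinant is non-positive inside the mask."""

    def __init__(self, count):
        super().__init__(f"deformation folds: {count} voxels with Jac <= 0")
        self.count = count


def tre(estimated: VectorField, landmarks: LandmarkSet, spacing=(1.0, 1.0, 1.0)) -> float:
    """Mean Euclidean landmark error in mm.

    The estimated field is sampled trilinearly at the landmark voxel
    coordinates, converted to mm with ``spacing``, and compared with the
    true per-landmark displacements.
    """
    pts = landmarks.points
    shape = estimated.shape
    if np.any(pts < 0) or np.any(pts > np.asarray(shape)[None, :] - 1):
        raise ValueError("landmarks outside the image bounds")
    coords = (pts[:, 0], pts[:, 1], pts[:, 2])
    est_mm = np.stack(
        [
            _sample_trilinear(estimated.components[c], coords, with_grad=False)
            * spacing[c]
            for c in range(3)
        ],
        axis=1,
    )
    return float(np.mean(np.linalg.norm(est_mm - landmarks.true_disp, axis=1)))


def endpoint_error(estimated: VectorField, truth: VectorField, mask=None) -> float:
    """Mean per-voxel Euclidean error against a dense truth field (voxels)."""
    err = np.sqrt(np.sum((estimated.components - truth.components) ** 2, axis=0))
    if mask is not None:
        err = err[np.asarray(mask, dtype=bool)]
    return float(err.mean())


def sdlogjac(u: VectorField, mask=None) -> float:
    """SD of ln Jac(u) over the mask: smoothness of volumetric change."""
    jac = jacobian_determinant(u)
    if mask is not None:
        jac = jac[np.asarray(mask, dtype=bool)]
    bad = int(np.count_nonzero(jac <= 0))
    if bad:
        raise FoldingError(bad)
    return float(np.log(jac).std())


def jac_deviation(u: VectorField, mask: np.ndarray) -> float:
    """Mean |Jac(u) - 1| over the mask after a 1-voxel erosion.

    The erosion excludes organ-boundary voxels, where sliding and partial
    voluming make the Jacobian numerically unreliable.
    """
    mask = np.asarray(mask, dtype=bool)
    eroded = binary_erosion(mask)
    if not eroded.any():
        raise ValueError("mask is empty after 1-voxel erosion")
    return float(np.abs(jacobian_determinant(u)[eroded] - 1.0).mean())


def dsc(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity coefficient 2|a & b| / (|a| + |b|); 1 if both empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("mask shapes must match")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def mean_curl_magnitude(u: VectorField, mask=None) -> float:
    """Mean Euclidean norm of curl(u) over the mask (per-voxel units)."""
    mag = curl(u).magnitude()
    if mask is not None:
        mag = mag[np.asarray(mask, dtype=bool)]
    return float(mag.mean())
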