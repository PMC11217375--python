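"""Synthetic test scenes with known ground-truth deformations.

The generators emulate the kinds of motion the registration is designed to
recover: smooth blob images stand in for anatomical contrast; radial fields
emulate irrotational expansion about a centre (the synthetic bladder
experiment); solenoidal fields (curls of a random potential) are
divergence-free by construction; B-spline fields interpolate random
control-point displacements, emulating deformations generated by displacing
randomly selected control points.

Conventions: every generator is deterministic given its seed; ``fixed`` is
built from ``moving`` as ``fixed(x) = moving(x + truth(x))``, so the
registration of (fixed, moving) has the exact solution ``u = truth``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter, zoom

from .fields import Volume, VectorField, curl, warp

__all__ = [
    "LandmarkSet",
    "SyntheticCase",
    "gen_blob_image",
    "gen_radial_field",
    "gen_solenoidal_field",
    "gen_bspline_field",
    "make_case",
    "sample_landmarks",
]


@dataclass
class LandmarkSet:
    """Point landmarks (voxel coordinates) with true displacements in mm."""

    points: np.ndarray  # (n, 3) voxel coordinates
    true_disp: np.ndarray  # (n, 3) displacements in mm

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=np.float64))
        self.true_disp = np.atleast_2d(np.asarray(self.true_disp, dtype=np.float64))
        if self.points.shape != self.true_disp.shape or self.points.shape[1] != 3:
            raise ValueError("points and true_disp must both be (n, 3)")
        if self.points.shape[0] == 0:
            raise ValueError("landmark set must be non-empty")

    def __len__(self):
        return self.points.shape[0]


@dataclass
class SyntheticCase:
    """A fixed/moving pair with the ground-truth displacement field."""

    fixed: Volume
    moving: Volume
    truth: VectorField
    seed: int
    kind: str

    def save(self, directory):
        """Write the case as NIfTI volumes + truth field + JSON metadata."""
        from .io import write_displacement, write_volume

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        write_volume(self.fixed, d / "fixed.nii.gz")
        write_volume(self.moving, d / "moving.nii.gz")
        write_displacement(self.truth, self.fixed, d / "truth.nii.gz")
        (d / "case.json").write_text(
            json.dumps({"seed": self.seed, "kind": self.kind})
        )


def gen_blob_image(shape, n_blobs: int = 12, seed: int = 0, noise_sd: float = 0.02) -> Volume:
    """Sum of random axis-aligned anisotropic Gaussians plus mild noise.

    Intensities are rescaled to [0, 1]; deterministic given ``seed``.
    """
    if min(shape) < 16:
        raise ValueError("all dimensions must be >= 16")
    rng = np.random.default_rng(seed)
    img = np.zeros(shape)
    axes = [np.arange(n, dtype=np.float64) for n in shape]
    for _ in range(n_blobs):
        center = [rng.uniform(0.15 * n, 0.85 * n) for n in shape]
        sigma = [rng.uniform(0.05 * n, 0.18 * n) for n in shape]
        amp = rng.uniform(0.3, 1.0)
        parts = [
            np.exp(-0.5 * ((ax - c) / s) ** 2) for ax, c, s in zip(axes, center, sigma)
        ]
        img += amp * parts[0][:, None, None] * parts[1][None, :, None] * parts[2][None, None, :]
    if n_blobs > 0:
        img += noise_sd * rng.standard_normal(shape)
        lo, hi = img.min(), img.max()
        img = (img - lo) / (hi - lo)
    return Volume(img)


def gen_radial_field(
    shape, center=None, peak: float = 3.0, radius: float = None, seed: int = 0
) -> VectorField:
    """A radial (irrotational) displacement away from ``center``.

    u = g(r) * (x - c) / r with the smooth compactly-supported profile
    g(r) = peak * (r / r0) * exp((1 - (r / r0)^2) / 2), r0 = radius / 2,
    which vanishes at the centre, peaks at r0 and decays rapidly beyond.
    Requires peak < radius / 2 so the map stays invertible.
    """
    if center is None:
        center = [(n - 1) / 2.0 for n in shape]
    if radius is None:
        radius = 0.4 * min(shape)
    if peak >= radius / 2:
        raise ValueError("need peak < radius / 2 for an invertible map")
    grids = np.meshgrid(*(np.arange(n, dtype=np.float64) for n in shape), indexing="ij")
    d = [g - c for g, c in zip(grids, center)]
    r = np.sqrt(sum(x**2 for x in d))
    r0 = radius / 2.0
    # g(r)/r is smooth at the origin, so build the per-component factor directly
    scale = (peak / r0) * np.exp(0.5 * (1.0 - (r / r0) ** 2))
    return VectorField.from_components(*(scale * x for x in d))


def gen_solenoidal_field(shape, amplitude: float = 2.0, seed: int = 0) -> VectorField:
    """u = curl(A) for a smooth random interior-supported potential A.

    Divergence-free by the discrete div(curl) = 0 identity (exact away from
    the boundary faces).  ``amplitude`` sets the maximum displacement norm.
    """
    rng = np.random.default_rng(seed)
    win = _interior_window(shape, margin=4)
    comps = []
    for _ in range(3):
        a = gaussian_filter(rng.standard_normal(shape), min(shape) / 8.0, mode="constant")
        comps.append(a * win)
    u = curl(VectorField.from_components(*comps))
    mag = u.magnitude().max()
    if mag > 0:
        u = VectorField(u.components * (amplitude / mag))
    return u


def _interior_window(shape, margin: int = 4) -> np.ndarray:
    """C1 window: 1 deep inside, smoothly to 0 within ``margin`` of a face."""
    parts = []
    for n in shape:
        x = np.arange(n, dtype=np.float64)
        w = np.minimum(x, n - 1 - x) / max(margin, 1)
        parts.append(np.clip(w, 0.0, 1.0) ** 2 * (3 - 2 * np.clip(w, 0.0, 1.0)))
    return parts[0][:, None, None] * parts[1][None, :, None] * parts[2][None, None, :]


def gen_bspline_field(
    shape,
    n_points: int = 1000,
    amplitude: float = 3.0,
    knot_spacing: int = 8,
    region_mask: np.ndarray = None,
    seed: int = 0,
) -> VectorField:
    """Random control-point displacements, cubic-spline interpolated densely.

    ``n_points`` control points on a coarse grid (knot spacing in voxels)
    receive random displacements of RMS ``amplitude`` voxels per component;
    the rest stay at zero.  ``region_mask`` restricts the displaced points
    to a region of interest.  The dense field is the cubic-spline (order 3)
    interpolation of the control grid, tapered to zero near the boundary.
    """
    if n_points < 0:
        raise ValueError("n_points must be >= 0")
    rng = np.random.default_rng(seed)
    cshape = tuple(max(4, int(np.ceil(n / knot_spacing)) + 1) for n in shape)
    ctrl = np.zeros((3, *cshape))
    centers = np.stack(
        np.meshgrid(*(np.linspace(0, n - 1, c) for n, c in zip(shape, cshape)), indexing="ij"),
        axis=-1,
    )
    flat_idx = np.arange(int(np.prod(cshape)))
    if region_mask is not None:
        pts = np.round(centers.reshape(-1, 3)).astype(int)
        ok = region_mask[pts[:, 0], pts[:, 1], pts[:, 2]]
        flat_idx = flat_idx[ok]
    n_sel = min(n_points, flat_idx.size)
    if n_sel > 0:
        sel = rng.choice(flat_idx, size=n_sel, replace=False)
        disp = amplitude * rng.standard_normal((n_sel, 3))
        for c in range(3):
            ch = np.zeros(int(np.prod(cshape)))
            ch[sel] = disp[:, c]
            ctrl[c] = ch.reshape(cshape)
    win = _interior_window(shape, margin=4)
    comps = []
    for c in range(3):
        dense = zoom(
            ctrl[c],
            [n / cs for n, cs in zip(shape, cshape)],
            order=3,
            mode="nearest",
            grid_mode=True,
        )
        comps.append(dense * win)
    return VectorField.from_components(*comps)


def make_case(
    kind: str,
    shape=(64, 64, 64),
    seed: int = 0,
    amplitude: float = 3.0,
    n_blobs: int = 12,
    **field_kwargs,
) -> SyntheticCase:
    """Build a registration test case of the given kind.

    The base blob image is the *moving* image; the fixed image is the
    moving image warped by the truth field, so the exact registration
    answer is ``u = truth``.  Kinds: ``radial``, ``solenoidal``,
    ``bspline``, ``translation``.
    """
    moving = gen_blob_image(shape, n_blobs=n_blobs, seed=seed)
    if kind == "radial":
        truth = gen_radial_field(shape, peak=amplitude, seed=seed, **field_kwargs)
    elif kind == "solenoidal":
        truth = gen_solenoidal_field(shape, amplitude=amplitude, seed=seed, **field_kwargs)
    elif kind == "bspline":
        truth = gen_bspline_field(shape, amplitude=amplitude, seed=seed + 1, **field_kwargs)
    elif kind == "translation":
        truth = VectorField(
            np.broadcast_to(
                np.array([amplitude, 0.0, 0.0])[:, None, None, None], (3, *shape)
            ).copy()
        )
    else:
        raise ValueError(f"unknown case kind {kind!r}")
    fixed = warp(moving, truth)
    return SyntheticCase(fixed, moving, truth, seed, kind)


def sample_landmarks(
    truth: VectorField, n: int = 100, spacing=(1.0, 1.0, 1.0), margin: int = 4, seed: int = 0
) -> LandmarkSet:
    """Random interior landmarks with true displacements from ``truth`` (mm)."""
    rng = np.random.default_rng(seed)
    shape = truth.shape
    pts = np.stack(
        [rng.uniform(margin, n_ - 1 - margin, size=n) for n_ in shape], axis=1
    )
    ipts = np.round(pts).astype(int)
    disp_vox = np.stack(
        [truth.components[c][ipts[:, 0], ipts[:, 1], ipts[:, 2]] for c in range(3)],
        axis=1,
    )
    return LandmarkSet(ipts.astype(float), disp_vox * np.asarray(spacing)[None, :])
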