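"""Discrete vector-field calculus on regular 3D grids.

This module defines the two core containers (:class:`Volume`,
:class:`VectorField`) and the finite-difference operators the registration
machinery is built on: divergence, curl, spatial gradient, the Jacobian
determinant of a displacement, and image warping by trilinear interpolation.

Conventions
-----------
* Array axes ``(0, 1, 2)`` are the spatial axes ``(x, y, z)``; vector
  component ``i`` displaces along array axis ``i``.
* All derivatives are taken per *voxel* (unit grid spacing).  Physical voxel
  spacing only enters at the I/O boundary and in landmark-error evaluation.
* Derivatives use second-order central differences in the interior and
  replicated-edge differences on the boundary faces (the array is padded by
  edge replication before the central stencil is applied).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Volume",
    "VectorField",
    "deriv",
    "divergence",
    "curl",
    "spatial_gradient",
    "jacobian_determinant",
    "warp",
    "warp_with_gradient",
]


@dataclass
class Volume:
    """A 3D scalar image with voxel spacing and origin in mm.

    Parameters
    ----------
    data:
        3D array of intensities, shape ``(n1, n2, n3)``.
    spacing:
        Per-axis voxel size in mm, strictly positive.
    origin:
        Per-axis offset of the first voxel centre in mm.
    """

    data: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3D, got shape {self.data.shape}")
        if min(self.data.shape) < 2:
            raise ValueError(f"all dimensions must be >= 2, got {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Volume contains non-finite values")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")

    @property
    def shape(self):
        return self.data.shape

    def like(self, data: np.ndarray) -> "Volume":
        """A new Volume with the same geometry but different data."""
        return Volume(data, self.spacing, self.origin)


@dataclass
class VectorField:
    """A displacement field in voxel units.

    ``components`` has shape ``(3, n1, n2, n3)``; component ``i`` is the
    displacement along array axis ``i``.
    """

    components: np.ndarray

    def __post_init__(self):
        self.components = np.asarray(self.components, dtype=np.float64)
        if self.components.ndim != 4 or self.components.shape[0] != 3:
            raise ValueError(
                f"VectorField expects shape (3, n1, n2, n3), got {self.components.shape}"
            )
        if not np.all(np.isfinite(self.components)):
            raise ValueError("VectorField contains non-finite values")

    @classmethod
    def from_components(cls, u1, u2, u3) -> "VectorField":
        u1, u2, u3 = (np.asarray(c, dtype=np.float64) for c in (u1, u2, u3))
        if not (u1.shape == u2.shape == u3.shape):
            raise ValueError("vector components must share a common shape")
        return cls(np.stack([u1, u2, u3]))

    @classmethod
    def zeros(cls, shape) -> "VectorField":
        return cls(np.zeros((3, *shape)))

    @property
    def shape(self):
        return self.components.shape[1:]

    def magnitude(self) -> np.ndarray:
        """Per-voxel Euclidean norm."""
        return np.sqrt(np.sum(self.components**2, axis=0))

    def __getitem__(self, i):
        return self.components[i]


def deriv(a: np.ndarray, axis: int) -> np.ndarray:
    """Central difference along ``axis`` with replicated-edge boundary.

    The array is padded by one voxel of edge replication so the same
    three-point stencil ``(a[i+1] - a[i-1]) / 2`` applies everywhere; on the
    two boundary faces this degenerates to a halved one-sided difference.
    """
    a = np.asarray(a, dtype=np.float64)
    pad = [(1, 1) if ax == axis else (0, 0) for ax in range(a.ndim)]
    ap = np.pad(a, pad, mode="edge")
    lo = [slice(None)] * a.ndim
    hi = [slice(None)] * a.ndim
    lo[axis] = slice(0, -2)
    hi[axis] = slice(2, None)
    return (ap[tuple(hi)] - ap[tuple(lo)]) / 2.0


def _deriv_t(a: np.ndarray, axis: int) -> np.ndarray:
    """Exact transpose of :func:`deriv` (replicated-edge central difference).

    Interior rows are the negated central difference; the first and last
    rows pick up the replicated-edge contributions (-(a0+a1)/2 and
    (a[n-2]+a[n-1])/2 respectively).  Needed by the adjoint-consistent
    gradient pullback.
    """
    a = np.asarray(a, dtype=np.float64)
    pad = [(1, 1) if ax == axis else (0, 0) for ax in range(a.ndim)]
    ap = np.pad(a, pad, mode="constant")
    lo = [slice(None)] * a.ndim
    hi = [slice(None)] * a.ndim
    lo[axis] = slice(0, -2)
    hi[axis] = slice(2, None)
    out = (ap[tuple(lo)] - ap[tuple(hi)]) / 2.0
    first = [slice(None)] * a.ndim
    last = [slice(None)] * a.ndim
    first[axis] = slice(0, 1)
    last[axis] = slice(-1, None)
    out[tuple(first)] -= a[tuple(first)] / 2.0
    out[tuple(last)] += a[tuple(last)] / 2.0
    return out


def divergence(u: VectorField) -> np.ndarray:
    """div u = du1/dx + du2/dy + du3/dz (per voxel)."""
    c = u.components
    return deriv(c[0], 0) + deriv(c[1], 1) + deriv(c[2], 2)


def curl(u: VectorField) -> VectorField:
    """curl u with the same differencing scheme as :func:`divergence`."""
    c = u.components
    return VectorField.from_components(
        deriv(c[2], 1) - deriv(c[1], 2),
        deriv(c[0], 2) - deriv(c[2], 0),
        deriv(c[1], 0) - deriv(c[0], 1),
    )


def spatial_gradient(image) -> VectorField:
    """Central-difference gradient of a scalar image (Volume or array)."""
    a = image.data if isinstance(image, Volume) else np.asarray(image)
    return VectorField.from_components(deriv(a, 0), deriv(a, 1), deriv(a, 2))


def jacobian_determinant(u: VectorField) -> np.ndarray:
    """Per-voxel det(I + grad u): the local volume-change factor.

    1 everywhere for the identity map; values <= 0 indicate folding.
    """
    c = u.components
    g = np.empty((3, 3, *u.shape))
    for i in range(3):
        for j in range(3):
            g[i, j] = deriv(c[i], j) + (1.0 if i == j else 0.0)
    return (
        g[0, 0] * (g[1, 1] * g[2, 2] - g[1, 2] * g[2, 1])
        - g[0, 1] * (g[1, 0] * g[2, 2] - g[1, 2] * g[2, 0])
        + g[0, 2] * (g[1, 0] * g[2, 1] - g[1, 1] * g[2, 0])
    )


def _sample_trilinear(vol: np.ndarray, coords, with_grad: bool):
    """Trilinear sampling of ``vol`` at ``coords`` (tuple of 3 arrays).

    Out-of-domain coordinates are clamped (replicated-edge values).  When
    ``with_grad`` is true also returns the exact gradient of the interpolant
    with respect to the sampling coordinates; the gradient is zero along a
    clamped coordinate, consistent with the clamped value.
    """
    n = vol.shape
    idx0, frac, inside = [], [], []
    for ax in range(3):
        c_raw = coords[ax]
        c = np.clip(c_raw, 0.0, n[ax] - 1.0)
        i0 = np.clip(np.floor(c).astype(np.intp), 0, n[ax] - 2)
        idx0.append(i0)
        frac.append(c - i0)
        inside.append((c_raw > 0.0) & (c_raw < n[ax] - 1.0))

    i0, j0, k0 = idx0
    fx, fy, fz = frac
    c000 = vol[i0, j0, k0]
    c100 = vol[i0 + 1, j0, k0]
    c010 = vol[i0, j0 + 1, k0]
    c110 = vol[i0 + 1, j0 + 1, k0]
    c001 = vol[i0, j0, k0 + 1]
    c101 = vol[i0 + 1, j0, k0 + 1]
    c011 = vol[i0, j0 + 1, k0 + 1]
    c111 = vol[i0 + 1, j0 + 1, k0 + 1]

    # interpolate along x, then y, then z
    c00 = c000 + fx * (c100 - c000)
    c01 = c001 + fx * (c101 - c001)
    c10 = c010 + fx * (c110 - c010)
    c11 = c011 + fx * (c111 - c011)
    c0 = c00 + fy * (c10 - c00)
    c1 = c01 + fy * (c11 - c01)
    val = c0 + fz * (c1 - c0)
    if not with_grad:
        return val

    # d/dx: difference along x, bilinear in (y, z)
    dx00 = c100 - c000
    dx01 = c101 - c001
    dx10 = c110 - c010
    dx11 = c111 - c011
    d0 = dx00 + fy * (dx10 - dx00)
    d1 = dx01 + fy * (dx11 - dx01)
    gx = (d0 + fz * (d1 - d0)) * inside[0]

    # d/dy: difference along y of the x-interpolated values
    gy0 = c10 - c00
    gy1 = c11 - c01
    gy = (gy0 + fz * (gy1 - gy0)) * inside[1]

    gz = (c1 - c0) * inside[2]
    return val, np.stack([gx, gy, gz])


def _warp_coords(shape, u: VectorField):
    grids = np.meshgrid(*(np.arange(n, dtype=np.float64) for n in shape), indexing="ij")
    return tuple(grids[i] + u.components[i] for i in range(3))


def warp(image: Volume, u: VectorField) -> Volume:
    """Resample ``image`` at x + u(x) by trilinear interpolation.

    Samples falling outside the domain use replicated-edge values.
    """
    if image.shape != u.shape:
        raise ValueError(f"image shape {image.shape} != field shape {u.shape}")
    val = _sample_trilinear(image.data, _warp_coords(image.shape, u), with_grad=False)
    return image.like(val)


def warp_with_gradient(image: Volume, u: VectorField):
    """Warp plus the exact interpolant gradient at the sample points.

    Returns ``(warped, grad)`` where ``grad`` is a :class:`VectorField`
    holding the analytic derivative of the trilinear interpolant of
    ``image`` with respect to each sampling coordinate, evaluated at
    x + u(x).  This is the exact Jacobian of the warp with respect to a
    per-voxel perturbation of ``u`` and is what similarity-metric gradients
    chain through.
    """
    if image.shape != u.shape:
        raise ValueError(f"image shape {image.shape} != field shape {u.shape}")
    val, g = _sample_trilinear(image.data, _warp_coords(image.shape, u), with_grad=True)
    return image.like(val), VectorField(g)
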