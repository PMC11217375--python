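"""Readers and writers for volumes, displacement fields, landmarks, config.

Conventions: in memory everything is 0-based, (x, y, z) axis order,
displacements in voxels.  Files store displacements in mm (voxel units
times spacing); DIR-lab-style landmark files are 1-based and converted on
read.  Supported image formats: NIfTI (.nii/.nii.gz) and MetaImage
(.mha/.mhd), via SimpleITK.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .fields import Volume, VectorField
from .synthetic import LandmarkSet

__all__ = [
    "read_volume",
    "write_volume",
    "read_displacement",
    "write_displacement",
    "read_landmarks",
    "landmarks_from_point_files",
    "load_config",
]

_IMAGE_SUFFIXES = (".nii", ".nii.gz", ".mha", ".mhd")


def _check_path(path) -> Path:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"no such file: {p}")
    return p


def read_volume(path) -> Volume:
    """Read a 3D scalar image; axes reordered to the internal (x, y, z)."""
    p = _check_path(path)
    name = p.name.lower()
    if not any(name.endswith(s) for s in _IMAGE_SUFFIXES):
        raise ValueError(f"unsupported image format: {p} (expected {_IMAGE_SUFFIXES})")
    img = sitk.ReadImage(str(p))
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    if arr.ndim != 3:
        raise ValueError(f"{p}: expected a 3D scalar image, got shape {arr.shape}")
    data = np.asarray(arr, dtype=np.float64).T  # -> (x, y, z)
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{p}: image contains non-finite voxels")
    return Volume(data, spacing=img.GetSpacing(), origin=img.GetOrigin())


def write_volume(vol: Volume, path) -> None:
    img = sitk.GetImageFromArray(vol.data.T)
    img.SetSpacing(vol.spacing)
    img.SetOrigin(vol.origin)
    sitk.WriteImage(img, str(path))


def write_displacement(u: VectorField, ref: Volume, path) -> None:
    """Write a displacement field as a vector image, components in mm."""
    if u.shape != ref.shape:
        raise ValueError("field and reference shapes must match")
    mm = np.stack(
        [u.components[c] * ref.spacing[c] for c in range(3)], axis=-1
    )  # (x, y, z, 3)
    img = sitk.GetImageFromArray(np.ascontiguousarray(mm.transpose(2, 1, 0, 3)), isVector=True)
    img.SetSpacing(ref.spacing)
    img.SetOrigin(ref.origin)
    sitk.WriteImage(img, str(path))


def read_displacement(path) -> tuple:
    """Read a displacement field; returns (VectorField in voxels, spacing)."""
    p = _check_path(path)
    img = sitk.ReadImage(str(p))
    arr = sitk.GetArrayFromImage(img)  # (z, y, x, 3) in mm
    if arr.ndim != 4 or arr.shape[-1] != 3:
        raise ValueError(f"{p}: expected a 3-component vector image, got {arr.shape}")
    spacing = img.GetSpacing()[:3]
    mm = np.asarray(arr, dtype=np.float64).transpose(2, 1, 0, 3)
    comps = [mm[..., c] / spacing[c] for c in range(3)]
    return VectorField.from_components(*comps), spacing


def read_landmarks(path, dialect: str = "dirlab") -> np.ndarray:
    """Read landmark voxel coordinates, (n, 3), 0-based.

    ``dirlab``: whitespace-separated triplets, 1-based indices (converted).
    ``csv``: comma-separated with an x,y,z header line, 0-based.
    """
    p = _check_path(path)
    pts = []
    with open(p) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    start = 0
    if dialect == "csv":
        start = 1  # header
    for ln_no, line in enumerate(lines[start:], start=start + 1):
        sep = "," if dialect == "csv" else None
        parts = line.split(sep)
        try:
            vals = [float(v) for v in parts]
        except ValueError:
            raise ValueError(f"{p}:{ln_no}: malformed landmark line {line!r}") from None
        if len(vals) != 3:
            raise ValueError(f"{p}:{ln_no}: expected 3 coordinates, got {len(vals)}")
        pts.append(vals)
    pts = np.asarray(pts, dtype=np.float64)
    if pts.size and dialect == "dirlab":
        pts -= 1.0
    return pts.reshape(-1, 3)


def landmarks_from_point_files(fixed_path, moving_path, spacing, dialect="dirlab") -> LandmarkSet:
    """Paired point files (fixed and moving positions) -> LandmarkSet.

    True displacement = (moving point - fixed point) * spacing, in mm.
    """
    pf = read_landmarks(fixed_path, dialect)
    pm = read_landmarks(moving_path, dialect)
    if pf.shape != pm.shape:
        raise ValueError(
            f"landmark files disagree in length: {pf.shape[0]} vs {pm.shape[0]}"
        )
    disp = (pm - pf) * np.asarray(spacing)[None, :]
    return LandmarkSet(pf, disp)


def load_config(path) -> dict:
    """Flat YAML config mirroring the CLI flag namespace."""
    import yaml

    p = _check_path(path)
    with open(p) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{p}: config must be a flat mapping")
    return cfg
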