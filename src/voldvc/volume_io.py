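"""Volumetric image and mask I/O.

A :class:`Volume` is a 3-D scalar intensity grid with an isotropic physical
voxel size in millimetres; a :class:`Mask` is a binary region-of-interest on
the same grid. NIfTI-1 (via nibabel) and multi-page TIFF stacks (via
tifffile) are supported. TIFF carries no voxel-size metadata, so loading a
TIFF stack requires the voxel size as an explicit argument — a silent
default would corrupt strain units downstream.

Index convention: 0-based voxel indices, array axes ``(x, y, z)``; a subset
window starting at ``s`` with edge ``N`` covers the half-open index range
``[s, s + N)`` along each axis. Voxel ``(i, j, k)`` has its centre at
``origin + (i, j, k) * voxel_size`` (mm).
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import nibabel as nib
import numpy as np
import tifffile

__all__ = [
    "Volume",
    "Mask",
    "load_volume",
    "save_volume",
    "load_mask",
    "save_mask",
    "check_compatible",
]

_VOXEL_TOL_MM = 1e-6


@dataclass
class Volume:
    """A 3-D scalar image with isotropic voxel size.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel intensities. Must be finite.
    voxel_size : float
        Edge length of a voxel in mm (isotropic).
    origin : tuple of float
        Physical coordinates (mm) of the centre of voxel (0, 0, 0).
    """

    data: np.ndarray
    voxel_size: float
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(f"Volume data must be 3-D, got shape {self.data.shape}")
        self.voxel_size = float(self.voxel_size)
        if not np.isfinite(self.voxel_size) or self.voxel_size <= 0:
            raise ValueError(f"voxel_size must be positive, got {self.voxel_size}")
        if not np.isfinite(np.asarray(self.data, dtype=np.float64)).all():
            raise ValueError("Volume data contains NaN or Inf")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def index_to_physical(self, idx: np.ndarray) -> np.ndarray:
        """Map (…, 3) voxel indices to physical mm coordinates."""
        return np.asarray(idx, dtype=np.float64) * self.voxel_size + np.asarray(
            self.origin
        )

    def grid_points(self) -> np.ndarray:
        """Physical coordinates (mm) of every voxel centre, shape (nx, ny, nz, 3)."""
        nx, ny, nz = self.shape
        pts = np.empty(self.shape + (3,), dtype=np.float64)
        pts[..., 0] = np.arange(nx, dtype=np.float64)[:, None, None]
        pts[..., 1] = np.arange(ny, dtype=np.float64)[None, :, None]
        pts[..., 2] = np.arange(nz, dtype=np.float64)[None, None, :]
        pts *= self.voxel_size
        pts += np.asarray(self.origin)
        return pts


@dataclass
class Mask:
    """Binary region-of-interest mask on the same grid as a companion Volume."""

    data: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"Mask data must be 3-D, got shape {arr.shape}")
        uniq = np.unique(arr)
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError(f"Mask must be 0/1-valued, found values {uniq[:10]}")
        if not arr.any():
            raise ValueError("Mask has no nonzero voxels")
        self.data = arr.astype(bool)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


def _infer_format(path: str | os.PathLike) -> str:
    name = str(path).lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith((".tif", ".tiff")):
        return "tiff_stack"
    raise ValueError(f"Cannot infer volume format from extension of {path!r}")


def load_volume(
    path: str | os.PathLike,
    format: str | None = None,
    voxel_size: float | None = None,
) -> Volume:
    """Read a volume from NIfTI or a multi-page TIFF stack.

    For NIfTI the voxel size is taken from the header and must be isotropic
    (anisotropic voxels are rejected: the correlation and strain machinery
    assumes a cubic voxel). For TIFF stacks, ``voxel_size`` is required.
    """
    fmt = format or _infer_format(path)
    if fmt == "nifti":
        img = nib.load(str(path))
        zooms = np.asarray(img.header.get_zooms()[:3], dtype=np.float64)
        if zooms.max() - zooms.min() > _VOXEL_TOL_MM:
            raise ValueError(
                f"Anisotropic voxels {tuple(zooms)} in {path!r}: this method "
                "requires isotropic voxels"
            )
        data = np.asanyarray(img.dataobj)
        if data.ndim == 4 and data.shape[3] == 1:
            data = data[..., 0]
        origin = tuple(np.asarray(img.affine[:3, 3], dtype=np.float64))
        return Volume(data, float(zooms[0]), origin)
    if fmt == "tiff_stack":
        if voxel_size is None:
            raise ValueError(
                "TIFF stacks carry no voxel-size metadata; pass voxel_size= explicitly"
            )
        arr = tifffile.imread(str(path))
        if arr.ndim != 3:
            raise ValueError(f"Expected a 3-D TIFF stack, got shape {arr.shape}")
        # pages are z slices; bring back to (x, y, z)
        return Volume(arr.transpose(2, 1, 0), float(voxel_size))
    raise ValueError(f"Unknown volume format {fmt!r}")


def save_volume(
    volume: Volume, path: str | os.PathLike, format: str | None = None
) -> None:
    """Write a volume so that :func:`load_volume` round-trips it.

    Intensities are preserved bit-exactly for integer dtypes; voxel size is
    stored in the NIfTI affine (TIFF stacks rely on the caller re-supplying
    it on load).
    """
    fmt = format or _infer_format(path)
    if fmt == "nifti":
        vs = volume.voxel_size
        affine = np.diag([vs, vs, vs, 1.0])
        affine[:3, 3] = volume.origin
        img = nib.Nifti1Image(np.asarray(volume.data), affine)
        img.set_data_dtype(volume.data.dtype)
        nib.save(img, str(path))
        return
    if fmt == "tiff_stack":
        tifffile.imwrite(
            str(path), volume.data.transpose(2, 1, 0), photometric="minisblack"
        )
        return
    raise ValueError(f"Unknown volume format {fmt!r}")


def load_mask(
    path: str | os.PathLike,
    format: str | None = None,
    voxel_size: float | None = None,
) -> Mask:
    vol = load_volume(path, format=format, voxel_size=voxel_size or 1.0)
    return Mask(vol.data)


def save_mask(mask: Mask, path: str | os.PathLike, voxel_size: float = 1.0) -> None:
    save_volume(Volume(mask.data.astype(np.uint8), voxel_size), path)


def check_compatible(a: Volume, b: Volume, mask: Mask | None = None) -> None:
    """Raise with a descriptive message unless a, b (and mask) share a grid."""
    if a.shape != b.shape:
        raise ValueError(f"Volume shapes differ: {a.shape} vs {b.shape}")
    if abs(a.voxel_size - b.voxel_size) > _VOXEL_TOL_MM:
        raise ValueError(
            f"Voxel sizes differ: {a.voxel_size} mm vs {b.voxel_size} mm"
        )
    if mask is not None:
        if mask.shape != a.shape:
            raise ValueError(
                f"Mask shape {mask.shape} does not match volume shape {a.shape}"
            )
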