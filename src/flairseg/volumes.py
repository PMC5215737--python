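"""Volumes and masks on a common voxel grid, with NIfTI-1 on-disk storage.

Conventions fixed here and relied on everywhere downstream:

* array axes are ``(x, y, z)`` as stored; axial slices for 2-D processing
  are ``data[:, :, k]``;
* voxel indices are 0-based;
* masks are stored on disk as unsigned 8-bit NIfTI, volumes as float32;
* two images are grid-compatible iff shapes match exactly and spacings
  match within a relative tolerance of 1e-5 (:func:`check_same_grid`).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

from .errors import GridMismatchError, NonBinaryMaskError, NotAVolumeError, VolumeIOError

__all__ = [
    "Volume",
    "BinaryMask",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "check_same_grid",
    "require_same_grid",
]

_SPACING_RTOL = 1e-5


@dataclass
class Volume:
    """A 3-D scalar intensity field with voxel spacing and spatial reference.

    Parameters
    ----------
    data
        3-D array of real intensities (arbitrary MRI units).
    spacing
        Voxel edge lengths in mm per axis, strictly positive.
    affine
        4x4 voxel-to-world matrix (NIfTI convention). Defaults to a
        diagonal affine built from ``spacing``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise NotAVolumeError(f"expected 3 axes, got {self.data.ndim}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume intensities must be finite")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 strictly positive lengths, got {self.spacing}")
        if self.affine is None:
            self.affine = np.diag(list(self.spacing) + [1.0])

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def with_data(self, data: np.ndarray) -> "Volume":
        """New volume with the same grid but different intensities."""
        return Volume(data=data, spacing=self.spacing, affine=self.affine.copy())


@dataclass
class BinaryMask:
    """Boolean labels on the same lattice as a :class:`Volume`."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise NotAVolumeError(f"expected 3 axes, got {arr.ndim}")
        if arr.dtype != bool:
            uniq = np.unique(arr)
            if not np.all(np.isin(uniq, (0, 1))):
                raise NonBinaryMaskError(f"non-binary mask: values {uniq[:10]}")
            arr = arr.astype(bool)
        self.data = arr
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 strictly positive lengths, got {self.spacing}")
        if self.affine is None:
            self.affine = np.diag(list(self.spacing) + [1.0])

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        """Number of foreground voxels."""
        return int(self.data.sum())

    def with_data(self, data: np.ndarray) -> "BinaryMask":
        return BinaryMask(data=data, spacing=self.spacing, affine=self.affine.copy())


def _load_nifti(path: str | os.PathLike) -> tuple[np.ndarray, tuple[float, ...], np.ndarray]:
    if not os.path.exists(path):
        raise VolumeIOError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises various types for malformed headers
        raise VolumeIOError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[:, :, :, 0]
    if data.ndim != 3:
        raise NotAVolumeError(f"{path}: not a 3-D volume (ndim={data.ndim})")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing, np.asarray(img.affine)


def read_volume(path: str | os.PathLike) -> Volume:
    """Read a 3-D intensity volume from a NIfTI-1 file."""
    data, spacing, affine = _load_nifti(path)
    return Volume(data=np.asarray(data, dtype=np.float32), spacing=spacing, affine=affine)


def write_volume(v: Volume, path: str | os.PathLike) -> None:
    """Write a volume as float32 NIfTI-1."""
    img = nib.Nifti1Image(np.asarray(v.data, dtype=np.float32), v.affine)
    img.header.set_zooms(v.spacing)
    nib.save(img, str(path))


def read_mask(path: str | os.PathLike) -> BinaryMask:
    """Read a binary mask; stored 0.0/1.0 floats are tolerated."""
    data, spacing, affine = _load_nifti(path)
    data = np.asarray(data)
    rounded = np.rint(data)
    if not np.allclose(data, rounded, atol=1e-6) or not np.all(np.isin(np.unique(rounded), (0, 1))):
        raise NonBinaryMaskError(f"{path}: non-binary mask")
    return BinaryMask(data=rounded.astype(bool), spacing=spacing, affine=affine)


def write_mask(m: BinaryMask, path: str | os.PathLike) -> None:
    """Write a mask as unsigned 8-bit NIfTI-1."""
    img = nib.Nifti1Image(m.data.astype(np.uint8), m.affine)
    img.header.set_zooms(m.spacing)
    nib.save(img, str(path))


def check_same_grid(a: Volume | BinaryMask, b: Volume | BinaryMask) -> bool:
    """True iff shapes are equal and spacings agree within relative tolerance."""
    if a.data.shape != b.data.shape:
        return False
    return bool(
        np.allclose(np.asarray(a.spacing), np.asarray(b.spacing), rtol=_SPACING_RTOL, atol=0.0)
    )


def require_same_grid(a: Volume | BinaryMask, b: Volume | BinaryMask, what: str = "images") -> None:
    """Raise :class:`GridMismatchError` unless the two images share a grid."""
    if not check_same_grid(a, b):
        raise GridMismatchError(
            f"{what} on incompatible grids: shape {a.data.shape} / spacing {a.spacing} "
            f"vs shape {b.data.shape} / spacing {b.spacing}"
        )
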