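"""Spatial image containers and NIfTI round-tripping.

The pipeline works on single-channel 3D MR volumes with an aligned binary
tumor mask.  Conventions used throughout the package:

* voxel indices are 0-based, array axis order is (z, y, x);
* ``spacing`` is the physical voxel size in mm per axis, same order;
* world coordinates are in mm (``origin + index * spacing``);
* masks are resampled nearest-neighbour and re-binarized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = ["ImageVolume", "TumorMask", "read_volume", "write_volume"]

#: 26-connectivity structuring element used for mask component checks.
CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=bool)

MIN_TUMOR_VOXELS = 64


@dataclass
class ImageVolume:
    """A 3D scalar grid with physical voxel spacing.

    Parameters
    ----------
    voxels : ndarray, shape (nz, ny, nx)
        Intensities in arbitrary units; must be finite.
    spacing : tuple of float
        Voxel size in mm per axis, all > 0.
    origin : tuple of float
        World coordinate (mm) of voxel (0, 0, 0).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError("volume must be 3D")
        if any(s < 8 for s in self.voxels.shape):
            raise ValueError(f"volume shape {self.voxels.shape} below (8,8,8)")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("volume contains non-finite intensities")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def copy_with(self, voxels: np.ndarray) -> "ImageVolume":
        return ImageVolume(voxels, self.spacing, self.origin)


@dataclass
class TumorMask:
    """Binary tumor delineation aligned to an :class:`ImageVolume`.

    Requires at least 64 foreground voxels forming a single 26-connected
    component (the delineation covers both enhanced and necrotic areas,
    so it is one region by construction).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise ValueError("mask must be 3D")
        n = int(self.voxels.sum())
        if n < MIN_TUMOR_VOXELS:
            raise ValueError(f"mask has {n} voxels, below the {MIN_TUMOR_VOXELS} minimum")
        _, ncomp = ndimage.label(self.voxels, structure=CONNECTIVITY_26)
        if ncomp != 1:
            raise ValueError(f"mask must be a single 26-connected component, found {ncomp}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())

    def check_aligned(self, volume: ImageVolume) -> None:
        if self.voxels.shape != volume.voxels.shape:
            raise ValueError(
                f"mask shape {self.voxels.shape} does not match volume {volume.voxels.shape}"
            )


def _affine(spacing, origin) -> np.ndarray:
    # nibabel stores x,y,z fastest-first; our arrays are (z,y,x)
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing[2], spacing[1], spacing[0]
    aff[:3, 3] = origin[2], origin[1], origin[0]
    return aff


def write_volume(path, volume) -> None:
    """Write an ImageVolume or TumorMask as NIfTI (.nii or .nii.gz)."""
    data = volume.voxels
    if data.dtype == bool:
        data = data.astype(np.uint8)
    # transpose to x,y,z order expected on disk
    img = nib.Nifti1Image(np.ascontiguousarray(data.T), _affine(volume.spacing, volume.origin))
    nib.save(img, str(path))


def read_volume(path, as_mask: bool = False):
    """Read a NIfTI file into an :class:`ImageVolume` (or :class:`TumorMask`)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj).T  # back to (z,y,x)
    zooms = img.header.get_zooms()[:3]
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    origin = tuple(float(v) for v in img.affine[:3, 3][::-1])
    cls = TumorMask if as_mask else ImageVolume
    return cls(data, spacing, origin)
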