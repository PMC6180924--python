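"""In-memory containers for PET-like volumes and segmentation masks.

An :class:`ImageVolume` is a 3D scalar grid of standardized uptake values
(SUV, body-weight normalized) together with its physical voxel spacing in
millimetres.  A :class:`VOIMask` is a boolean grid congruent with its parent
volume marking the segmented tumor (the volume of interest).  Both round-trip
through NIfTI via nibabel, with the spacing carried in the affine.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np

__all__ = ["ImageVolume", "VOIMask"]


@dataclass
class ImageVolume:
    """A 3D SUV grid with voxel spacing.

    Parameters
    ----------
    data:
        3D array of finite, nonnegative SUV values, axis order (x, y, z).
    spacing_mm:
        Physical voxel size along each axis, strictly positive.
    origin_mm:
        Physical coordinate of the (0, 0, 0) voxel centre.
    """

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.data.shape}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be 3 positive reals, got {self.spacing_mm}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        if np.any(self.data < 0):
            raise ValueError("SUV values must be nonnegative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing_mm) + [1.0])
        aff[:3, 3] = self.origin_mm
        return aff

    def to_nifti(self, path: str) -> None:
        """Write the volume as NIfTI, spacing encoded in the affine."""
        img = nib.Nifti1Image(self.data.astype(np.float32), self.affine)
        nib.save(img, path)

    @classmethod
    def from_nifti(cls, path: str) -> "ImageVolume":
        img = nib.load(path)
        data = np.asarray(img.get_fdata(), dtype=float)
        zooms = img.header.get_zooms()[:3]
        origin = tuple(float(v) for v in img.affine[:3, 3])
        return cls(data=data, spacing_mm=tuple(float(z) for z in zooms), origin_mm=origin)


@dataclass
class VOIMask:
    """Boolean tumor mask aligned with an :class:`ImageVolume`."""

    mask: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {self.mask.shape}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be positive, got {self.spacing_mm}")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def volume_ml(self) -> float:
        """Physical mask volume: voxel count x (dx*dy*dz) / 1000."""
        return self.n_voxels * float(np.prod(self.spacing_mm)) / 1000.0

    def to_nifti(self, path: str) -> None:
        aff = np.diag(list(self.spacing_mm) + [1.0])
        aff[:3, 3] = self.origin_mm
        img = nib.Nifti1Image(self.mask.astype(np.uint8), aff)
        nib.save(img, path)

    @classmethod
    def from_nifti(cls, path: str) -> "VOIMask":
        img = nib.load(path)
        data = np.asarray(img.get_fdata())
        zooms = img.header.get_zooms()[:3]
        origin = tuple(float(v) for v in img.affine[:3, 3])
        return cls(mask=data > 0.5, spacing_mm=tuple(float(z) for z in zooms),
                   origin_mm=origin)
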