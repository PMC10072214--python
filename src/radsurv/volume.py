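"""3D image volumes and binary VOI masks with physical spacing.

The whole pipeline works on a minimal grid model: a 3D scalar array
(HU for CT, Gy for dose), per-axis voxel spacing in millimetres, and an
origin. Masks are boolean arrays on the same grid. Volumes round-trip
through NIfTI-1 with a diagonal affine built from spacing and origin.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["ImageVolume", "VOIMask", "read_volume", "read_mask"]


@dataclass(frozen=True)
class ImageVolume:
    """A 3D scalar grid with physical spacing (mm) and origin (mm)."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {values.shape}")
        if not np.all(np.isfinite(values)):
            raise ValueError("volume contains non-finite values")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def with_values(self, values: np.ndarray) -> "ImageVolume":
        """Same grid, new voxel values."""
        return ImageVolume(values, self.spacing, self.origin)


@dataclass(frozen=True)
class VOIMask:
    """Binary volume of interest aligned with an :class:`ImageVolume`."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        values = np.asarray(self.values).astype(bool)
        if values.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {values.shape}")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())

    def check_aligned(self, vol: ImageVolume) -> None:
        if self.shape != vol.shape or not np.allclose(self.spacing, vol.spacing):
            raise ValueError(
                f"mask grid {self.shape}@{self.spacing} does not match "
                f"volume grid {vol.shape}@{vol.spacing}"
            )


def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def write_volume(vol: ImageVolume | VOIMask, path: str | Path) -> None:
    """Write a volume or mask as NIfTI; masks are stored as uint8."""
    arr = vol.values
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    img = nib.Nifti1Image(arr, _affine(vol.spacing, vol.origin))
    nib.save(img, str(path))


def read_volume(path: str | Path) -> ImageVolume:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(o) for o in img.affine[:3, 3])
    return ImageVolume(np.asarray(img.dataobj, dtype=np.float64), spacing, origin)


def read_mask(path: str | Path) -> VOIMask:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(o) for o in img.affine[:3, 3])
    return VOIMask(np.asarray(img.dataobj) > 0.5, spacing, origin)
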