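"""In-memory image containers shared by every pipeline stage.

Two thin wrappers around a numpy array plus a NIfTI-style grid-to-world
affine: :class:`ImageVolume` for scalar images (MRI, PET) and
:class:`LabelVolume` for integer-coded parcellations.  All world
coordinates are millimetres; transforms elsewhere in the package act on
world coordinates, never on voxel indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["ImageVolume", "LabelVolume", "centered_affine"]


def centered_affine(shape: tuple[int, int, int], spacing: tuple[float, float, float]) -> np.ndarray:
    """Grid-to-world affine placing the world origin at the grid centre.

    The mid-sagittal plane x = 0 then sits exactly between the two central
    voxel columns (even shapes) or on the central column (odd shapes), so
    mirrored anatomy is mirror-symmetric in voxel space as well.
    """
    shape = np.asarray(shape, dtype=float)
    spacing = np.asarray(spacing, dtype=float)
    affine = np.eye(4)
    affine[:3, :3] = np.diag(spacing)
    affine[:3, 3] = -(shape - 1) / 2.0 * spacing
    return affine


@dataclass
class ImageVolume:
    """3-D scalar grid with voxel spacing and a grid-to-world affine."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D volume, got shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def spacing(self) -> np.ndarray:
        """Voxel edge lengths in mm (norms of the affine columns)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def copy_with(self, data: np.ndarray) -> "ImageVolume":
        return type(self)(data=np.asarray(data), affine=self.affine.copy())

    def save(self, path: str | Path) -> None:
        nib.save(nib.Nifti1Image(self.data.astype(np.float32), self.affine), str(path))

    @classmethod
    def load(cls, path: str | Path) -> "ImageVolume":
        img = nib.load(str(path))
        return cls(data=np.asarray(img.get_fdata(), dtype=np.float64), affine=np.asarray(img.affine))


@dataclass
class LabelVolume:
    """Integer-coded parcellation on the same grid model as ImageVolume."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if not np.issubdtype(data.dtype, np.integer):
            rounded = np.rint(data)
            if not np.allclose(data, rounded):
                raise ValueError("label volume must hold integer codes")
            data = rounded
        self.data = data.astype(np.int32)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D volume, got shape {self.data.shape}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def spacing(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def codes(self) -> np.ndarray:
        return np.unique(self.data)

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        return ImageVolume.voxel_to_world(self, ijk)  # type: ignore[arg-type]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        return ImageVolume.world_to_voxel(self, xyz)  # type: ignore[arg-type]

    def save(self, path: str | Path) -> None:
        nib.save(nib.Nifti1Image(self.data.astype(np.int16), self.affine), str(path))

    @classmethod
    def load(cls, path: str | Path) -> "LabelVolume":
        img = nib.load(str(path))
        return cls(data=np.rint(np.asarray(img.get_fdata())).astype(np.int32), affine=np.asarray(img.affine))
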