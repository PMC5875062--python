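"""Atlas label propagation, ROI binary masks, and voxel-vector extraction.

Analysis happens on the template (atlas) grid: each subject's PET is
resampled into template space, where the ten region masks are defined
once.  ROI voxel intensities are gathered in ascending linear-index order
of the analysis grid so that the same column always refers to the same
(region, voxel-rank) position across subjects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .phantom import ROI_CODES
from .resampling import resample
from .transforms import AffineTransform
from .volume import ImageVolume, LabelVolume

__all__ = [
    "ROIDefinition",
    "MaskSet",
    "ROIVector",
    "default_roi_definitions",
    "load_roi_definitions",
    "warp_labels",
    "extract_masks",
    "extract_roi_vector",
    "extract_subject_vectors",
]


@dataclass(frozen=True)
class ROIDefinition:
    name: str
    code: int


def default_roi_definitions() -> tuple[ROIDefinition, ...]:
    """The ten bilateral staging regions with their phantom atlas codes."""
    return tuple(ROIDefinition(name, code) for name, code in sorted(ROI_CODES.items()))


def load_roi_definitions(path: str | Path) -> tuple[ROIDefinition, ...]:
    """Read a JSON list of {"name": ..., "code": ...} region entries."""
    entries = json.loads(Path(path).read_text())
    rois = tuple(ROIDefinition(e["name"], int(e["code"])) for e in entries)
    if len({(r.name, r.code) for r in rois}) != len(rois):
        raise ValueError("ROI definitions must be unique")
    return rois


@dataclass
class MaskSet:
    """Binary masks per ROI plus their union, all on the analysis grid."""

    masks: dict[str, np.ndarray]
    affine: np.ndarray

    def __post_init__(self) -> None:
        total = None
        for name, mask in self.masks.items():
            if mask.dtype != bool:
                raise ValueError(f"mask {name!r} must be boolean")
            if not mask.any():
                raise ValueError(f"mask {name!r} is empty")
            overlap = mask if total is None else (total & mask)
            if total is not None and overlap.any():
                raise ValueError(f"mask {name!r} overlaps another mask")
            total = mask.copy() if total is None else (total | mask)

    @property
    def combined(self) -> np.ndarray:
        out = np.zeros(next(iter(self.masks.values())).shape, dtype=bool)
        for mask in self.masks.values():
            out |= mask
        return out

    def names(self) -> list[str]:
        return sorted(self.masks)


@dataclass
class ROIVector:
    roi: str
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float).ravel()

    def __len__(self) -> int:
        return self.intensities.size


def warp_labels(
    atlas: LabelVolume,
    template_to_subject: AffineTransform,
    subject_grid: ImageVolume | LabelVolume,
) -> LabelVolume:
    """Propagate atlas codes onto a subject grid by nearest-neighbour resampling."""
    return resample(atlas, template_to_subject, reference=subject_grid, interp="nearest")


def extract_masks(labels: LabelVolume, rois: tuple[ROIDefinition, ...] | None = None) -> MaskSet:
    """Binary mask per ROI code; missing codes raise an error naming the region."""
    rois = rois if rois is not None else default_roi_definitions()
    masks = {}
    for roi in rois:
        mask = labels.data == roi.code
        if not mask.any():
            raise ValueError(f"atlas is missing ROI {roi.name!r} (code {roi.code})")
        masks[roi.name] = mask
    return MaskSet(masks=masks, affine=labels.affine.copy())


def extract_roi_vector(pet_norm: ImageVolume, mask: np.ndarray, roi: str = "") -> ROIVector:
    """Masked voxel intensities in ascending linear-index order."""
    if pet_norm.data.shape != mask.shape:
        raise ValueError("PET volume and mask are on different grids")
    if not mask.any():
        raise ValueError(f"mask for ROI {roi!r} is empty")
    flat = pet_norm.data.ravel(order="C")
    idx = np.flatnonzero(mask.ravel(order="C"))
    return ROIVector(roi=roi, intensities=flat[idx])


def extract_subject_vectors(pet_norm: ImageVolume, mask_set: MaskSet) -> dict[str, ROIVector]:
    """All ten ROI vectors for one subject, keyed by region name."""
    return {
        name: extract_roi_vector(pet_norm, mask_set.masks[name], roi=name)
        for name in mask_set.names()
    }


def vectors_to_csv(vectors: dict[str, ROIVector], path: str | Path) -> None:
    rows = []
    for name in sorted(vectors):
        for rank, value in enumerate(vectors[name].intensities):
            rows.append({"roi": name, "voxel_rank": rank, "intensity": value})
    pd.DataFrame(rows).to_csv(path, index=False)
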