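"""Resampling of image and label volumes through world-space affines."""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .transforms import AffineTransform
from .volume import ImageVolume, LabelVolume

__all__ = ["resample"]


def resample(
    moving: ImageVolume | LabelVolume,
    transform: AffineTransform,
    reference: ImageVolume | LabelVolume,
    interp: str = "trilinear",
) -> ImageVolume | LabelVolume:
    """Resample `moving` onto the grid of `reference` under `transform`.

    `transform` maps moving-world to fixed(reference)-world coordinates, so
    each output voxel x takes the value moving(transform⁻¹(x)).  Voxels
    mapping outside the moving field of view are set to 0.  Use
    ``interp="nearest"`` for label volumes (codes are never interpolated).
    """
    if interp not in ("trilinear", "nearest"):
        raise ValueError(f"unknown interpolation {interp!r}")
    if isinstance(moving, LabelVolume) and interp != "nearest":
        raise ValueError("label volumes must be resampled with nearest-neighbour interpolation")

    # output index -> ref world -> moving world -> moving index
    index_map = (
        np.linalg.inv(moving.affine)
        @ np.linalg.inv(transform.matrix)
        @ reference.affine
    )
    order = 1 if interp == "trilinear" else 0
    data = ndimage.affine_transform(
        moving.data.astype(np.float64),
        matrix=index_map[:3, :3],
        offset=index_map[:3, 3],
        output_shape=reference.shape,
        order=order,
        mode="constant",
        cval=0.0,
        prefilter=False,
    )
    if isinstance(moving, LabelVolume):
        return LabelVolume(np.rint(data).astype(np.int32), reference.affine.copy())
    return ImageVolume(data, reference.affine.copy())
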