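"""Padded subject × voxel feature matrices.

Each subject contributes one ROI voxel vector per region; region vectors
are padded with zeros to the cohort-wide maximum length of that region, so
the matrix width is

    D = Σ_i max_j |k_ij|

over regions i and subjects j.  The block map records which columns belong
to which region, and zero padding keeps column c meaning "voxel-rank r of
region i" for every subject.  A whole-brain variant uses every voxel that
is non-zero in at least one subject.  Mean-centering is fit on a chosen
row subset (training folds) to avoid information leaking from held-out
subjects, and longitudinal fusion concatenates the two visits row-wise,
doubling the width when both visits share a pipeline variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .parcellate import ROIVector
from .volume import ImageVolume

__all__ = [
    "FeatureMatrix",
    "roi_max_lengths",
    "assemble",
    "assemble_wholebrain",
    "mean_center",
    "concat_timepoints",
]


@dataclass
class FeatureMatrix:
    X: np.ndarray
    subjects: list[str]
    block_map: dict[str, tuple[int, int]] = field(default_factory=dict)  # roi -> (start, stop)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if self.X.shape[0] != len(self.subjects):
            raise ValueError("row count must equal subject count")

    @property
    def width(self) -> int:
        return self.X.shape[1]

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    def block(self, roi: str) -> np.ndarray:
        start, stop = self.block_map[roi]
        return self.X[:, start:stop]


def roi_max_lengths(cohort: list[dict[str, ROIVector]]) -> dict[str, int]:
    """Per-region maximum voxel count over all subjects."""
    if not cohort:
        raise ValueError("cohort is empty")
    names = sorted(cohort[0])
    lengths = {name: 0 for name in names}
    for j, vectors in enumerate(cohort):
        if sorted(vectors) != names:
            raise ValueError(f"subject {j} is missing ROIs: expected {names}, got {sorted(vectors)}")
        for name in names:
            lengths[name] = max(lengths[name], len(vectors[name]))
    return lengths


def assemble(
    cohort: list[dict[str, ROIVector]],
    subjects: list[str] | None = None,
    k_max: dict[str, int] | None = None,
) -> FeatureMatrix:
    """Concatenate zero-padded region blocks into the subjects × D matrix."""
    k_max = k_max if k_max is not None else roi_max_lengths(cohort)
    names = sorted(k_max)
    subjects = subjects if subjects is not None else [f"S{j:04d}" for j in range(len(cohort))]

    block_map, start = {}, 0
    for name in names:
        block_map[name] = (start, start + k_max[name])
        start += k_max[name]
    width = start

    X = np.zeros((len(cohort), width))
    for j, vectors in enumerate(cohort):
        for name in names:
            vec = vectors[name].intensities
            lo, hi = block_map[name]
            if vec.size > k_max[name]:
                raise ValueError(
                    f"ROI {name!r} of subject {subjects[j]} has {vec.size} voxels, "
                    f"exceeding the block length {k_max[name]}"
                )
            X[j, lo:lo + vec.size] = vec
    return FeatureMatrix(X=X, subjects=list(subjects), block_map=block_map)


def assemble_wholebrain(volumes: list[ImageVolume], subjects: list[str] | None = None) -> FeatureMatrix:
    """One column per grid voxel that is non-zero in at least one subject."""
    if not volumes:
        raise ValueError("no volumes supplied")
    shape = volumes[0].shape
    for v in volumes:
        if v.shape != shape:
            raise ValueError("all volumes must share the analysis grid")
    stack = np.stack([v.data.ravel(order="C") for v in volumes])
    support = np.flatnonzero(np.any(stack != 0, axis=0))
    subjects = subjects if subjects is not None else [f"S{j:04d}" for j in range(len(volumes))]
    return FeatureMatrix(
        X=stack[:, support],
        subjects=list(subjects),
        block_map={"wholebrain": (0, support.size)},
    )


def mean_center(X: FeatureMatrix, fit_rows: np.ndarray | list[int] | None = None) -> FeatureMatrix:
    """Subtract column means computed on `fit_rows` from every row."""
    fit_rows = np.arange(X.n_subjects) if fit_rows is None else np.asarray(fit_rows, dtype=int)
    if fit_rows.size == 0:
        raise ValueError("fit_rows must be nonempty")
    means = X.X[fit_rows].mean(axis=0)
    return FeatureMatrix(X=X.X - means, subjects=list(X.subjects), block_map=dict(X.block_map))


def concat_timepoints(X1: FeatureMatrix, X2: FeatureMatrix) -> FeatureMatrix:
    """Row-wise fuse two visits: width D1 + D2, doubling when D1 = D2."""
    if X2.width == 0:
        return FeatureMatrix(X=X1.X.copy(), subjects=list(X1.subjects), block_map=dict(X1.block_map))
    if X1.subjects != X2.subjects:
        raise ValueError("timepoint matrices must list the same subjects in the same order")
    block_map = dict(X1.block_map)
    for name, (lo, hi) in X2.block_map.items():
        block_map[f"{name}@2"] = (X1.width + lo, X1.width + hi)
    return FeatureMatrix(
        X=np.hstack([X1.X, X2.X]),
        subjects=list(X1.subjects),
        block_map=block_map,
    )
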