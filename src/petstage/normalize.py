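"""Histogram-based PET intensity normalization.

PET units are scanner- and dose-dependent, so voxel intensities must be
brought to a common scale before subjects can be compared voxel-wise.  The
rule implemented here derives two constants from the image itself:

* ``T_max`` — the upper edge of the 10th of 50 equal-width histogram bins
  computed over the strictly positive voxels.  Everything at or below this
  threshold is treated as low-valued background outside the brain.
* ``I_max`` — the mean intensity of all voxels strictly above ``T_max``.

The volume is then divided by ``I_max``.  Because ``I_max`` is a robust
upper-level mean rather than the single hottest voxel, saturated outlier
voxels cannot compress the useful dynamic range: typical brain tissue
lands near 1 and only the hottest voxels exceed it.  The mapping is
invariant under global positive rescaling of the input, since both
constants scale with the image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import ImageVolume

__all__ = [
    "HistogramSpec",
    "NormalizationResult",
    "DegenerateHistogramError",
    "compute_tmax",
    "compute_imax",
    "normalize_volume",
]


class DegenerateHistogramError(ValueError):
    """The positive-intensity support is empty or constant."""


@dataclass(frozen=True)
class HistogramSpec:
    n_bins: int = 50
    threshold_bin: int = 10  # 1-based bin index

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be at least 2")
        if not (1 <= self.threshold_bin <= self.n_bins):
            raise ValueError("threshold_bin must lie in [1, n_bins]")


@dataclass
class NormalizationResult:
    t_max: float
    i_max: float
    volume: ImageVolume


def _positive_voxels(volume: ImageVolume) -> np.ndarray:
    values = volume.data[volume.data > 0]
    if values.size == 0:
        raise DegenerateHistogramError("volume has no strictly positive voxels")
    return values


def compute_tmax(volume: ImageVolume, spec: HistogramSpec = HistogramSpec()) -> float:
    """Upper edge of the threshold bin of the positive-intensity histogram.

    Equal-width bins over [min, max] of the strictly positive voxels give
    ``T_max = min + threshold_bin * (max - min) / n_bins``.
    """
    values = _positive_voxels(volume)
    lo, hi = float(values.min()), float(values.max())
    if hi <= lo:
        raise DegenerateHistogramError("positive voxels are constant; histogram is degenerate")
    if values.size < spec.n_bins:
        raise DegenerateHistogramError(
            f"need at least {spec.n_bins} positive voxels, got {values.size}"
        )
    return lo + spec.threshold_bin * (hi - lo) / spec.n_bins


def compute_imax(volume: ImageVolume, t_max: float) -> float:
    """Arithmetic mean of voxels strictly greater than ``t_max``."""
    upper = volume.data[volume.data > t_max]
    if upper.size == 0:
        raise ValueError(f"no voxel lies strictly above T_max = {t_max}")
    return float(upper.mean())


def normalize_volume(volume: ImageVolume, spec: HistogramSpec = HistogramSpec()) -> NormalizationResult:
    """Scale a PET volume by the histogram rule.

    Output voxels are ``max(v, 0) / I_max``; non-positive input maps to
    zero and typical tissue lands near 1.  Grid shape and affine are
    unchanged.
    """
    t_max = compute_tmax(volume, spec)
    i_max = compute_imax(volume, t_max)
    data = np.clip(volume.data, 0.0, None) / i_max
    return NormalizationResult(t_max=t_max, i_max=i_max, volume=volume.copy_with(data))
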