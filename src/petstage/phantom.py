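"""Synthetic PET/MRI head phantom and cohort generator.

The phantom is a nested-ellipsoid head (background / CSF shell / WM shell /
GM core) with five bilateral ellipsoidal uptake regions embedded in the GM
core, mirroring the five region pairs used for staging Alzheimer's disease:
anterior cingulum, posterior cingulum, inferior frontal / orbitofrontal,
precuneus and lateral temporal cortex.  FDG phantoms express diagnosis-
dependent hypometabolism inside the regions (AD < LMCI < EMCI < NC) and
AV45 phantoms the opposite ordering of amyloid accumulation; a 12-month
second visit multiplies the regional signal by a per-diagnosis progression
factor.  All geometry is specified in world millimetres, so the same
anatomy can be rendered on any grid size.

Every generator is a pure function of (config, seed): per-scan random
streams are derived by stable hashing of (master seed, subject, tracer,
timepoint), so cohorts are reproducible scan by scan.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .transforms import AffineTransform, params_to_matrix
from .volume import ImageVolume, LabelVolume, centered_affine
from .resampling import resample

__all__ = [
    "PhantomConfig",
    "CohortSpec",
    "SubjectRecord",
    "LandmarkSet",
    "PhantomConfigError",
    "DIAGNOSES",
    "TRACERS",
    "TIMEPOINTS",
    "ROI_CODES",
    "TISSUE_CODES",
    "build_template",
    "simulate_mri",
    "simulate_pet",
    "perturb_pose",
    "place_landmarks",
    "simulate_cohort",
]

DIAGNOSES = ("AD", "EMCI", "LMCI", "NC")
TRACERS = ("FDG", "AV45")
TIMEPOINTS = ("baseline", "second_visit")

TISSUE_CODES = {"background": 0, "CSF": 1, "WM": 2, "GM": 3}

_ROI_BASENAMES = (
    "anterior_cingulum",
    "posterior_cingulum",
    "inferior_frontal",
    "precuneus",
    "lateral_temporal",
)
# left = negative world x; codes 11..20, left/right interleaved
ROI_CODES = {}
for _i, _base in enumerate(_ROI_BASENAMES):
    ROI_CODES[f"{_base}_left"] = 11 + 2 * _i
    ROI_CODES[f"{_base}_right"] = 12 + 2 * _i


class PhantomConfigError(ValueError):
    """Invalid phantom geometry or parameters."""


_DEFAULT_HEAD_RADII = (42.0, 50.0, 38.0)


def _default_roi_geometry() -> dict[str, tuple[tuple[float, float, float], tuple[float, float, float]]]:
    """Per-ROI (centre, radii) in mm for the five bilateral pairs.

    ROI centres sit in the middle of the cortical GM ribbon, at 77 % of
    the head radius along anatomically evocative directions.  Centres are
    given for the right (+x) member; the left member is the mirror image
    across the mid-sagittal plane x = 0.
    """
    head = np.asarray(_DEFAULT_HEAD_RADII)
    directions = {
        "anterior_cingulum": (0.25, 0.90, 0.36),
        "posterior_cingulum": (0.25, -0.90, 0.36),
        "inferior_frontal": (0.65, 0.70, -0.30),
        "precuneus": (0.35, -0.75, 0.56),
        "lateral_temporal": (0.95, 0.10, -0.30),
    }
    radii = (4.5, 4.5, 4.5)
    geometry = {}
    for base, d in directions.items():
        n = np.asarray(d) / np.linalg.norm(d)
        cx, cy, cz = 0.77 * n * head
        geometry[f"{base}_right"] = ((float(cx), float(cy), float(cz)), radii)
        geometry[f"{base}_left"] = ((float(-cx), float(cy), float(cz)), radii)
    return geometry


def _default_effect_table() -> dict[tuple[str, str], float]:
    # FDG: regional hypometabolism deepens with disease stage;
    # AV45: amyloid accumulation grows with stage.
    return {
        ("AD", "FDG"): 0.75,
        ("LMCI", "FDG"): 0.85,
        ("EMCI", "FDG"): 0.92,
        ("NC", "FDG"): 1.00,
        ("AD", "AV45"): 1.25,
        ("LMCI", "AV45"): 1.15,
        ("EMCI", "AV45"): 1.08,
        ("NC", "AV45"): 1.00,
    }


def _default_progression_table() -> dict[tuple[str, str], float]:
    # Multiplier on the regional signal at the 12-month second visit.
    return {
        ("AD", "FDG"): 0.88,
        ("LMCI", "FDG"): 0.93,
        ("EMCI", "FDG"): 0.97,
        ("NC", "FDG"): 1.00,
        ("AD", "AV45"): 1.12,
        ("LMCI", "AV45"): 1.07,
        ("EMCI", "AV45"): 1.03,
        ("NC", "AV45"): 1.00,
    }


@dataclass
class MisalignRanges:
    """Half-widths of the uniform pose-sampling box for PET–MRI misalignment."""

    rotation_deg: float = 10.0
    translation_mm: float = 10.0
    scale: float = 0.10  # half-width on the log-scale axes (≈ ±10 %)
    shear: float = 0.10


@dataclass
class PhantomConfig:
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    # T1-like MRI tissue means (WM bright) and PET uptake means (GM hot)
    tissue_means: dict[str, float] = field(
        default_factory=lambda: {"background": 0.0, "CSF": 25.0, "WM": 110.0, "GM": 80.0}
    )
    pet_uptake_means: dict[str, float] = field(
        default_factory=lambda: {"background": 0.0, "CSF": 10.0, "WM": 30.0, "GM": 70.0}
    )
    # anatomically ordered shells: thin CSF layer under the skull, then the
    # cortical GM ribbon (the PET-bright tissue), then the WM core
    head_radii: tuple[float, float, float] = _DEFAULT_HEAD_RADII
    csf_fraction: float = 0.92  # GM ribbon starts at this fraction of head_radii
    wm_fraction: float = 0.62  # WM core starts at this fraction
    # the WM core is shifted off-centre and CSF ventricles are carved into
    # it: without such internal structure the concentric shells are nearly
    # rotation-invariant and the registration problem would be degenerate
    wm_center_offset: tuple[float, float, float] = (0.0, -2.0, 1.0)
    ventricle_geometry: dict = field(
        default_factory=lambda: {
            "ventricle_right": ((7.0, -5.0, 0.0), (4.0, 9.0, 5.0)),
            "ventricle_left": ((-7.0, -5.0, 0.0), (4.0, 9.0, 5.0)),
        }
    )
    # sulcus-like WM fingers into the GM ribbon and deep-nuclei GM blobs in
    # the WM core give the template the irregular internal detail real
    # brains have; without it the interior is featureless and intensity
    # metrics cannot pin down rotation, scale and shear.  Template anatomy,
    # fixed by its own seed and shared by every subject.
    n_structure_blobs: int = 30
    n_core_blobs: int = 12
    structure_seed: int = 1234
    roi_geometry: dict = field(default_factory=_default_roi_geometry)
    effect_table: dict = field(default_factory=_default_effect_table)
    progression_table: dict = field(default_factory=_default_progression_table)
    noise_sd: float = 2.0
    smoothing_fwhm: float = 8.0
    misalign_ranges: MisalignRanges = field(default_factory=MisalignRanges)
    misalign_model: str = "rigid"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.grid_shape) < 16:
            raise PhantomConfigError("grid_shape must be at least 16 voxels per axis")
        if min(self.spacing) <= 0:
            raise PhantomConfigError("spacing must be positive")
        if self.smoothing_fwhm < 0:
            raise PhantomConfigError("smoothing_fwhm must be non-negative")
        if any(f <= 0 for f in self.effect_table.values()):
            raise PhantomConfigError("effect factors must be positive")
        for name, (_, radii) in self.roi_geometry.items():
            if min(radii) <= 0:
                raise PhantomConfigError(f"ROI {name!r} has a non-positive radius")

    @property
    def affine(self) -> np.ndarray:
        return centered_affine(self.grid_shape, self.spacing)


@dataclass
class CohortSpec:
    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"AD": 99, "EMCI": 164, "LMCI": 189, "NC": 208}
    )
    tracers: tuple[str, ...] = ("FDG", "AV45")
    timepoints: tuple[str, ...] = ("baseline", "second_visit")
    # (mean, sd) per diagnosis per timepoint
    mmse_params: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {
            "AD": {"baseline": (22.9, 2.2), "second_visit": (20.4, 4.1)},
            "EMCI": {"baseline": (28.5, 1.4), "second_visit": (27.7, 2.7)},
            "LMCI": {"baseline": (27.6, 1.8), "second_visit": (24.4, 4.9)},
            "NC": {"baseline": (29.1, 1.2), "second_visit": (28.3, 2.3)},
        }
    )

    def __post_init__(self) -> None:
        for group, n in self.n_per_group.items():
            if group not in DIAGNOSES:
                raise ValueError(f"unknown diagnosis {group!r}")
            if n < 0:
                raise ValueError("group counts must be non-negative")
        for tracer in self.tracers:
            if tracer not in TRACERS:
                raise ValueError(f"unknown tracer {tracer!r}")
        for tp in self.timepoints:
            if tp not in TIMEPOINTS:
                raise ValueError(f"unknown timepoint {tp!r}")
        for group_params in self.mmse_params.values():
            for mean, sd in group_params.values():
                if not (0 <= mean <= 30) or sd < 0:
                    raise ValueError("MMSE parameters must lie in [0, 30] with sd >= 0")

    @property
    def total_subjects(self) -> int:
        return sum(self.n_per_group.values())


@dataclass
class SubjectRecord:
    """One manifest row: a single scan of a subject."""

    subject_id: str
    diagnosis: str
    tracer: str
    timepoint: str
    mmse: float
    mri_path: str = ""
    pet_path: str = ""
    truth_transform_path: str = ""
    truth_transform: AffineTransform | None = None


@dataclass
class LandmarkSet:
    """Named 3-D points in world mm."""

    points: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if not self.points:
            raise ValueError("a landmark set needs at least one point")
        self.points = {k: np.asarray(v, dtype=float).reshape(3) for k, v in self.points.items()}
        for name, p in self.points.items():
            if not np.all(np.isfinite(p)):
                raise ValueError(f"landmark {name!r} has non-finite coordinates")

    def __len__(self) -> int:
        return len(self.points)

    def names(self) -> list[str]:
        return sorted(self.points)

    def as_array(self, names: list[str] | None = None) -> np.ndarray:
        names = names if names is not None else self.names()
        return np.stack([self.points[n] for n in names])

    def transformed(self, t: AffineTransform) -> "LandmarkSet":
        names = self.names()
        moved = t.apply(self.as_array(names))
        return LandmarkSet({n: moved[i] for i, n in enumerate(names)})

    def save(self, path: str | Path) -> None:
        rows = [{"name": n, "x_mm": p[0], "y_mm": p[1], "z_mm": p[2]} for n, p in sorted(self.points.items())]
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def load(cls, path: str | Path) -> "LandmarkSet":
        df = pd.read_csv(path)
        return cls({r["name"]: np.array([r.x_mm, r.y_mm, r.z_mm]) for r in df.itertuples(index=False)})


# ---------------------------------------------------------------------------
# geometry


def _world_grid(config: PhantomConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    affine = config.affine
    axes = [
        affine[d, d] * np.arange(config.grid_shape[d]) + affine[d, 3]
        for d in range(3)
    ]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid_mask(grid, center, radii) -> np.ndarray:
    x, y, z = grid
    cx, cy, cz = center
    rx, ry, rz = radii
    return ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 + ((z - cz) / rz) ** 2 <= 1.0


def build_template(config: PhantomConfig) -> tuple[ImageVolume, LabelVolume]:
    """Render the noise-free MRI-like template and its label volume.

    The label volume carries the four tissue codes plus ten distinct ROI
    codes; bilateral ROI pairs are exact mirror images across x = 0.
    Raises :class:`PhantomConfigError` if ROI ellipsoids overlap each other
    or escape the GM core.
    """
    grid = _world_grid(config)
    head = np.asarray(config.head_radii, dtype=float)

    labels = np.zeros(config.grid_shape, dtype=np.int32)
    labels[_ellipsoid_mask(grid, (0, 0, 0), head)] = TISSUE_CODES["CSF"]
    gm_ribbon_outer = _ellipsoid_mask(grid, (0, 0, 0), head * config.csf_fraction)
    labels[gm_ribbon_outer] = TISSUE_CODES["GM"]
    wm_core = _ellipsoid_mask(grid, config.wm_center_offset, head * config.wm_fraction)
    labels[wm_core] = TISSUE_CODES["WM"]
    gm_ribbon = gm_ribbon_outer & ~wm_core

    ventricles = np.zeros(config.grid_shape, dtype=bool)
    for name, (center, radii) in config.ventricle_geometry.items():
        mask = _ellipsoid_mask(grid, center, radii)
        if not np.all(wm_core[mask]):
            raise PhantomConfigError(f"ventricle {name!r} does not fit inside the WM core")
        ventricles |= mask
    labels[ventricles] = TISSUE_CODES["CSF"]

    roi_masks = {}
    for name, (center, radii) in config.roi_geometry.items():
        if name not in ROI_CODES:
            raise PhantomConfigError(f"unknown ROI name {name!r}")
        mask = _ellipsoid_mask(grid, center, radii)
        if not mask.any():
            raise PhantomConfigError(f"ROI {name!r} contains no voxels at this resolution")
        if not np.all(gm_ribbon[mask]):
            raise PhantomConfigError(f"ROI {name!r} does not fit inside the cortical GM ribbon")
        roi_masks[name] = mask
    all_rois = np.zeros(config.grid_shape, dtype=bool)
    for mask in roi_masks.values():
        all_rois |= mask

    # internal texture: sulcus-like WM fingers into the GM ribbon and
    # deep-nuclei GM islands in the WM core, steering clear of ventricles
    # and ROIs
    blob_rng = np.random.default_rng(config.structure_seed)

    def place_blobs(count: int, host_code: int, blob_code: int, frac_lo: float, frac_hi: float,
                    r_lo: float, r_hi: float) -> None:
        host = labels == host_code
        placed = attempts = 0
        while placed < count and attempts < 50 * max(count, 1):
            attempts += 1
            u = blob_rng.uniform(-1, 1, 3)
            frac = blob_rng.uniform(frac_lo, frac_hi)
            center = u / max(np.linalg.norm(u), 1e-9) * frac * head
            radii = blob_rng.uniform(r_lo, r_hi, 3)
            mask = _ellipsoid_mask(grid, center, radii)
            if mask.any() and np.all(host[mask]) and not np.any(all_rois[mask]):
                labels[mask] = blob_code
                host[mask] = False
                placed += 1

    place_blobs(config.n_structure_blobs, TISSUE_CODES["GM"], TISSUE_CODES["WM"],
                config.wm_fraction + 0.03, config.csf_fraction - 0.03, 2.5, 5.0)
    place_blobs(config.n_core_blobs, TISSUE_CODES["WM"], TISSUE_CODES["GM"],
                0.05, config.wm_fraction - 0.10, 3.0, 6.0)

    names = sorted(roi_masks)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if np.any(roi_masks[a] & roi_masks[b]):
                raise PhantomConfigError(f"ROIs {a!r} and {b!r} overlap")

    for name, mask in roi_masks.items():
        labels[mask] = ROI_CODES[name]

    affine = config.affine
    template = _render_tissue_image(labels, config.tissue_means, roi_as="GM")
    return ImageVolume(template, affine), LabelVolume(labels, affine)


def _render_tissue_image(labels: np.ndarray, means: dict[str, float], roi_as: str = "GM") -> np.ndarray:
    out = np.zeros(labels.shape, dtype=np.float64)
    for tissue, code in TISSUE_CODES.items():
        out[labels == code] = means[tissue]
    roi_value = means[roi_as]
    for code in ROI_CODES.values():
        out[labels == code] = roi_value
    return out


def _check_labels(labels: LabelVolume) -> None:
    known = set(TISSUE_CODES.values()) | set(ROI_CODES.values())
    unknown = set(np.unique(labels.data)) - known
    if unknown:
        raise ValueError(f"label volume contains unknown codes {sorted(unknown)}")


# ---------------------------------------------------------------------------
# scan simulators


def simulate_mri(labels: LabelVolume, config: PhantomConfig, seed: int) -> ImageVolume:
    """Piecewise-constant tissue image plus additive zero-mean Gaussian noise."""
    _check_labels(labels)
    rng = np.random.default_rng(seed)
    data = _render_tissue_image(labels.data, config.tissue_means)
    if config.noise_sd > 0:
        data = data + rng.normal(0.0, config.noise_sd, size=data.shape)
    return ImageVolume(data, labels.affine)


def simulate_pet(
    labels: LabelVolume,
    diagnosis: str,
    tracer: str,
    timepoint: str,
    config: PhantomConfig,
    seed: int,
) -> ImageVolume:
    """Tracer-uptake image with diagnosis-dependent regional effects.

    Regional GM uptake is multiplied by the (diagnosis, tracer) effect
    factor — and additionally by the progression factor at the second
    visit — then smoothed with an isotropic Gaussian of
    ``config.smoothing_fwhm`` mm FWHM, then degraded with additive noise.
    Values are clipped at zero.
    """
    _check_labels(labels)
    key = (diagnosis, tracer)
    if key not in config.effect_table:
        raise KeyError(f"no effect-table entry for {key}")
    factor = config.effect_table[key]
    if timepoint == "second_visit":
        factor *= config.progression_table.get(key, 1.0)
    elif timepoint != "baseline":
        raise ValueError(f"unknown timepoint {timepoint!r}")

    data = _render_tissue_image(labels.data, config.pet_uptake_means)
    roi = np.isin(labels.data, list(ROI_CODES.values()))
    data[roi] = config.pet_uptake_means["GM"] * factor

    if config.smoothing_fwhm > 0:
        sigma_vox = config.smoothing_fwhm / 2.355 / np.asarray(labels.spacing)
        data = ndimage.gaussian_filter(data, sigma=sigma_vox)
    if config.noise_sd > 0:
        rng = np.random.default_rng(seed)
        data = data + rng.normal(0.0, config.noise_sd, size=data.shape)
    return ImageVolume(np.clip(data, 0.0, None), labels.affine)


def sample_pose(config: PhantomConfig, model: str, rng: np.random.Generator) -> AffineTransform:
    """Draw a random pose uniformly within the configured misalignment box."""
    r = config.misalign_ranges
    params = [rng.uniform(-r.rotation_deg, r.rotation_deg, 3), rng.uniform(-r.translation_mm, r.translation_mm, 3)]
    if model == "affine":
        params += [rng.uniform(-r.scale, r.scale, 3), rng.uniform(-r.shear, r.shear, 3)]
    elif model != "rigid":
        raise ValueError(f"unknown pose model {model!r}")
    matrix = params_to_matrix(np.concatenate(params), model, center=np.zeros(3))
    return AffineTransform(matrix, model=model)


def perturb_pose(
    volume: ImageVolume,
    model: str,
    config: PhantomConfig,
    seed: int,
) -> tuple[ImageVolume, AffineTransform]:
    """Apply a random rigid/affine pose to a volume, returning the truth.

    The returned transform maps original-space world points to perturbed-
    space world points; the perturbed volume is resampled on the input grid.
    """
    rng = np.random.default_rng(seed)
    truth = sample_pose(config, model, rng)
    moved = resample(volume, truth, reference=volume, interp="trilinear")
    return moved, truth


def place_landmarks(labels: LabelVolume) -> LandmarkSet:
    """One landmark per ROI at its world-space centroid."""
    points = {}
    for name, code in ROI_CODES.items():
        idx = np.argwhere(labels.data == code)
        if idx.size == 0:
            continue
        points[name] = labels.voxel_to_world(idx.mean(axis=0))[0]
    if not points:
        raise ValueError("label volume contains no ROI codes")
    return LandmarkSet(points)


# ---------------------------------------------------------------------------
# cohort


def _scan_seed(master: int, subject_id: str, tracer: str, timepoint: str) -> int:
    token = f"{master}|{subject_id}|{tracer}|{timepoint}".encode()
    return zlib.crc32(token) & 0x7FFFFFFF


from functools import lru_cache


@lru_cache(maxsize=None)
def _calibrated_mmse_loc(mean: float, sd: float) -> float:
    """Location for a [0, 30]-truncated normal whose truncated mean is `mean`.

    Truncation at the ceiling pulls the mean down, so the untruncated
    location must sit above the target for high-scoring groups.
    """
    from scipy.optimize import brentq

    def truncated_mean(loc: float) -> float:
        a, b = (0.0 - loc) / sd, (30.0 - loc) / sd
        return float(stats.truncnorm.mean(a, b, loc=loc, scale=sd))

    return float(brentq(lambda loc: truncated_mean(loc) - mean, mean - 5 * sd, mean + 5 * sd))


def _sample_mmse(spec: CohortSpec, diagnosis: str, timepoint: str, rng: np.random.Generator) -> float:
    mean, sd = spec.mmse_params[diagnosis][timepoint]
    if sd == 0:
        return float(mean)
    loc = _calibrated_mmse_loc(mean, sd)
    a, b = (0.0 - loc) / sd, (30.0 - loc) / sd
    return float(stats.truncnorm.rvs(a, b, loc=loc, scale=sd, random_state=rng))


def simulate_cohort(
    spec: CohortSpec,
    config: PhantomConfig,
    seed: int,
    out_dir: str | Path | None = None,
    materialize: bool = True,
    misalign: bool = True,
) -> list[SubjectRecord]:
    """Generate a full cohort: one manifest row per (subject, tracer, timepoint).

    With ``materialize=True`` (requires ``out_dir``), NIfTI volumes, truth
    transforms (4x4 JSON), the template/atlas, landmarks and a manifest CSV
    are written to disk.  With ``materialize=False`` only the records and
    manifest are produced — useful for cohort bookkeeping.  ``misalign=False``
    keeps every PET aligned with its MRI (identity ground truth).
    """
    if spec.total_subjects == 0:
        raise ValueError("cohort must contain at least one subject")
    if materialize and out_dir is None:
        raise ValueError("materialize=True requires out_dir")

    out = Path(out_dir) if out_dir is not None else None
    template = atlas = None
    if materialize:
        out.mkdir(parents=True, exist_ok=True)
        template, atlas = build_template(config)
        template.save(out / "template.nii.gz")
        atlas.save(out / "atlas.nii.gz")
        place_landmarks(atlas).save(out / "landmarks.csv")

    records: list[SubjectRecord] = []
    for diagnosis in DIAGNOSES:
        for k in range(spec.n_per_group.get(diagnosis, 0)):
            subject_id = f"{diagnosis}_{k:04d}"
            subj_rng = np.random.default_rng(_scan_seed(seed, subject_id, "-", "-"))
            mmse = {tp: _sample_mmse(spec, diagnosis, tp, subj_rng) for tp in spec.timepoints}

            mri_path = ""
            if materialize:
                mri = simulate_mri(atlas, config, _scan_seed(seed, subject_id, "MRI", "-"))
                mri_path = str(out / f"{subject_id}_mri.nii.gz")
                mri.save(mri_path)

            for tracer in spec.tracers:
                for timepoint in spec.timepoints:
                    scan_seed = _scan_seed(seed, subject_id, tracer, timepoint)
                    pet_path = truth_path = ""
                    truth = AffineTransform.identity(config.misalign_model)
                    if materialize:
                        pet = simulate_pet(atlas, diagnosis, tracer, timepoint, config, scan_seed)
                        if misalign:
                            pet, truth = perturb_pose(pet, config.misalign_model, config, scan_seed + 1)
                        pet_path = str(out / f"{subject_id}_{tracer}_{timepoint}_pet.nii.gz")
                        pet.save(pet_path)
                        truth_path = str(out / f"{subject_id}_{tracer}_{timepoint}_truth.json")
                        truth.save(truth_path)
                    records.append(
                        SubjectRecord(
                            subject_id=subject_id,
                            diagnosis=diagnosis,
                            tracer=tracer,
                            timepoint=timepoint,
                            mmse=round(mmse[timepoint], 1),
                            mri_path=mri_path,
                            pet_path=pet_path,
                            truth_transform_path=truth_path,
                            truth_transform=truth if materialize else None,
                        )
                    )

    if out is not None:
        manifest_records(records).to_csv(out / "manifest.csv", index=False)
    return records


def manifest_records(records: list[SubjectRecord]) -> pd.DataFrame:
    cols = ["subject_id", "diagnosis", "tracer", "timepoint", "mmse", "mri_path", "pet_path", "truth_transform_path"]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records], columns=cols)
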