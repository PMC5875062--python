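"""End-to-end study orchestration.

``run_study`` drives the full chain — cohort simulation, PET intensity
normalization, (optional) PET–MRI registration, atlas parcellation,
feature assembly and cross-validated classification — and writes a report
directory containing the registration-configuration benchmark and the
pairwise classification tables, plus a run manifest with the config hash.
Everything is a pure function of (config, master seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import phantom as ph
from .classify import rbf_svm, random_forest
from .evaluate import ExperimentSpec, run_pairwise_experiment
from .features import FeatureMatrix, assemble, assemble_wholebrain
from .normalize import HistogramSpec, normalize_volume
from .parcellate import extract_masks, extract_subject_vectors
from .register import RegistrationConfig, compare_configs, make_benchmark_pairs, register
from .resampling import resample
from .transforms import AffineTransform
from .volume import ImageVolume

__all__ = ["StudyConfig", "run_study", "write_report", "build_feature_matrices"]


@dataclass
class StudyConfig:
    phantom: ph.PhantomConfig = field(default_factory=ph.PhantomConfig)
    cohort: ph.CohortSpec = field(default_factory=ph.CohortSpec)
    histogram: HistogramSpec = field(default_factory=HistogramSpec)
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    experiments: list[ExperimentSpec] = field(default_factory=list)
    benchmark_pairs: int = 16
    misalign: bool = False
    alignment: str = "truth"  # none | truth | register — how PET returns to template space
    out_dir: str = "study_out"
    seed: int = 0

    def config_hash(self) -> str:
        blob = json.dumps(_as_jsonable(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _as_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _as_jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {str(k): _as_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _pet_to_template(record: ph.SubjectRecord, template: ImageVolume, alignment: str,
                     reg_config: RegistrationConfig) -> ImageVolume:
    pet = ImageVolume.load(record.pet_path)
    if alignment == "none":
        return pet
    if alignment == "truth":
        truth = record.truth_transform or AffineTransform.load(record.truth_transform_path)
        return resample(pet, truth.invert(), reference=template)
    if alignment == "register":
        mri = ImageVolume.load(record.mri_path)
        recovered = register(mri, pet, reg_config)
        return resample(pet, recovered, reference=template)
    raise ValueError(f"unknown alignment mode {alignment!r}")


def build_feature_matrices(
    records: list[ph.SubjectRecord],
    template: ImageVolume,
    atlas,
    tracer: str,
    histogram: HistogramSpec = HistogramSpec(),
    alignment: str = "truth",
    reg_config: RegistrationConfig = RegistrationConfig(),
    approach: str = "multiregion",
) -> tuple[dict[str, FeatureMatrix], np.ndarray]:
    """Per-timepoint feature matrices for one tracer, plus subject diagnoses.

    Subject rows are ordered by subject id and identical across timepoints,
    as required for longitudinal concatenation.
    """
    mask_set = extract_masks(atlas)
    by_tp: dict[str, dict[str, object]] = {}
    diag_by_subject: dict[str, str] = {}
    for rec in records:
        if rec.tracer != tracer:
            continue
        pet = _pet_to_template(rec, template, alignment, reg_config)
        pet_norm = normalize_volume(pet, histogram).volume
        diag_by_subject[rec.subject_id] = rec.diagnosis
        if approach == "multiregion":
            payload = extract_subject_vectors(pet_norm, mask_set)
        elif approach == "wholebrain":
            payload = pet_norm
        else:
            raise ValueError(f"unknown approach {approach!r}")
        by_tp.setdefault(rec.timepoint, {})[rec.subject_id] = payload

    subjects = sorted(diag_by_subject)
    matrices = {}
    for tp, per_subject in by_tp.items():
        ordered = [per_subject[s] for s in subjects]
        if approach == "multiregion":
            matrices[tp] = assemble(ordered, subjects=subjects)
        else:
            matrices[tp] = assemble_wholebrain(ordered, subjects=subjects)
    diagnoses = np.array([diag_by_subject[s] for s in subjects])
    return matrices, diagnoses


def default_experiments(seed: int = 0) -> list[ExperimentSpec]:
    classifiers = (rbf_svm(), random_forest(seed=seed))
    return [
        ExperimentSpec(pair=("AD", "NC"), tracer="FDG", timepoint_mode=mode, classifiers=classifiers, seed=seed)
        for mode in ("baseline", "combined")
    ] + [
        ExperimentSpec(pair=("EMCI", "LMCI"), tracer="FDG", timepoint_mode="baseline",
                       classifiers=classifiers, seed=seed)
    ]


def run_study(config: StudyConfig) -> dict:
    """Execute every stage in order and write all report files.

    Returns a dict with the registration benchmark table, the
    classification results table, and the path of the report directory.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    experiments = config.experiments or default_experiments(config.seed)

    cohort_dir = out / "cohort"
    records = ph.simulate_cohort(
        config.cohort, config.phantom, config.seed,
        out_dir=cohort_dir, materialize=True, misalign=config.misalign,
    )
    template = ImageVolume.load(cohort_dir / "template.nii.gz")
    from .volume import LabelVolume
    atlas = LabelVolume.load(cohort_dir / "atlas.nii.gz")

    benchmark = None
    if config.benchmark_pairs > 0:
        pairs = make_benchmark_pairs(config.phantom, n_pairs=config.benchmark_pairs,
                                     model="affine", seed=config.seed)
        benchmark = compare_configs(pairs)

    result_frames = []
    tracers_needed = {e.tracer for e in experiments}
    for tracer in sorted(tracers_needed):
        matrices, diagnoses = build_feature_matrices(
            records, template, atlas, tracer,
            histogram=config.histogram,
            alignment=config.alignment if config.misalign else "truth",
            reg_config=config.registration,
        )
        for exp in experiments:
            if exp.tracer != tracer:
                continue
            result_frames.append(run_pairwise_experiment(matrices, diagnoses, exp))
    results = pd.concat(result_frames, ignore_index=True) if result_frames else pd.DataFrame()

    report = {"benchmark": benchmark, "classification": results, "out_dir": str(out)}
    write_report(report, config)
    return report


def write_report(report: dict, config: StudyConfig) -> None:
    """Serialize benchmark and classification tables plus a run manifest."""
    out = Path(report["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    if report.get("benchmark") is not None:
        report["benchmark"].to_csv(out / "registration_benchmark.tsv", sep="\t", index=False)
    results = report.get("classification")
    if results is not None and len(results):
        table = results.drop(columns=["predictions", "y_true"], errors="ignore")
        table.to_csv(out / "classification_results.tsv", sep="\t", index=False)
        (out / "classification_results.json").write_text(
            table.to_json(orient="records", indent=2)
        )
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "config": _as_jsonable(config),
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
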