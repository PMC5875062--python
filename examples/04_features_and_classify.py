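"""Multiregion features and cross-validated EMCI-vs-LMCI classification.

Simulates an FDG cohort (12 early + 12 late MCI, two visits), extracts the ten
ROI voxel vectors per scan, assembles the zero-padded feature matrix,
and scores an RBF-SVM and a random forest with stratified 10-fold CV —
at baseline alone and with both visits concatenated.
"""

import numpy as np

from petstage import (
    PhantomConfig,
    build_template,
    extract_masks,
    extract_subject_vectors,
    normalize_volume,
    simulate_pet,
)
from petstage.classify import random_forest, rbf_svm
from petstage.evaluate import cross_validate
from petstage.features import assemble, concat_timepoints

config = PhantomConfig(grid_shape=(32,) * 3, spacing=(4.0,) * 3)
_, atlas = build_template(config)
masks = extract_masks(atlas)

rng = np.random.default_rng(0)
subjects, diagnoses = [], []
per_tp = {"baseline": [], "second_visit": []}
for diagnosis in ("EMCI", "LMCI"):
    for k in range(12):
        subjects.append(f"{diagnosis}_{k}")
        diagnoses.append(diagnosis)
        for tp in per_tp:
            pet = simulate_pet(atlas, diagnosis, "FDG", tp, config, seed=int(rng.integers(2**31)))
            per_tp[tp].append(extract_subject_vectors(normalize_volume(pet).volume, masks))

X_base = assemble(per_tp["baseline"], subjects=subjects)
X_second = assemble(per_tp["second_visit"], subjects=subjects)
X_combined = concat_timepoints(X_base, X_second)
y = np.array(diagnoses)

print(f"feature width D = {X_base.width} (baseline), {X_combined.width} (combined: doubled)\n")
for name, spec in (("RBF-SVM", rbf_svm()), ("random forest", random_forest(seed=0))):
    for label, X in (("baseline", X_base), ("combined", X_combined)):
        res = cross_validate(spec, X, y, positive="LMCI", folds=6, seed=0)
        m = res["metrics"]
        print(f"{name:13s} {label:9s} ACC {m.acc * 100:5.1f}%  SEN {m.sen * 100:5.1f}%  "
              f"SPE {m.spe * 100:5.1f}%  AUC {m.auc:.3f}")
print("\nLate MCI shows deeper regional hypometabolism than early MCI; the")
print("12-month visit adds a further-progressed snapshot of the same regions.")
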