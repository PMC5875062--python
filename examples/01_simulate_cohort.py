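"""Simulate a small synthetic PET/MRI cohort and inspect its manifest.

Builds an 8-subject FDG cohort (2 per diagnostic group) on a 32³ grid,
writes NIfTI volumes, ground-truth transforms, landmarks and a manifest
CSV, then prints the per-group MMSE summary.  MMSE scores follow the
group- and visit-specific distributions of the study population, so AD
subjects score around 23 at baseline and decline by the second visit.
"""

import tempfile
from pathlib import Path

from petstage import CohortSpec, PhantomConfig, simulate_cohort
from petstage.phantom import manifest_records

out = Path(tempfile.mkdtemp(prefix="petstage_cohort_"))
config = PhantomConfig(grid_shape=(32,) * 3, spacing=(4.0,) * 3)
spec = CohortSpec(n_per_group={"AD": 2, "EMCI": 2, "LMCI": 2, "NC": 2}, tracers=("FDG",))

records = simulate_cohort(spec, config, seed=0, out_dir=out)
df = manifest_records(records)

print(f"wrote {len(records)} scans for {df.subject_id.nunique()} subjects to {out}\n")
print(df[df.timepoint == "baseline"].groupby("diagnosis").mmse.agg(["count", "mean"]).round(1))
print("\nMMSE means track the study's cohort table: AD lowest, NC near ceiling.")
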