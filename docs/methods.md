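# Methods

`petstage` implements a multiregion PET classification pipeline for
staging Alzheimer's disease (AD, late and early mild cognitive
impairment, normal controls) from FDG- and AV45-PET, together with a
synthetic PET/MRI cohort generator that provides ground truth for every
stage.  This note records the models, the defaults and why they were
chosen, and what the synthetic validation does and does not establish.

## The head phantom

The template is a nested-ellipsoid head in world millimetres, rendered
onto any requested grid (default 64³ at 2 mm; tests use 32³/48³ over the
same 128 mm box).  Shells follow anatomical order from outside in: a thin
CSF rim (from 92 % of the head radii), the cortical grey-matter ribbon
(92 %–62 %), and a white-matter core whose centre is shifted 2 mm
posterior and 1 mm superior.  Mirror-symmetric lateral-ventricle CSF
ellipsoids are carved into the core.  Deterministic "texture" —
sulcus-like WM fingers in the ribbon and deep-nuclei GM islands in the
core, placed by a dedicated structure seed shared by all subjects — gives
the template the irregular internal detail that real brains have.
Without it, concentric shells are nearly rotation-invariant and
intensity-based registration is degenerate; an earlier design with a
solid bright GM core also let affine registration lower its cost by
magnifying the smoothed PET ~13 %, an artifact of the dome-shaped
intensity profile that a cortical ribbon does not produce.

Ten ellipsoidal uptake regions (the five bilateral pairs used for AD
staging: anterior cingulum, posterior cingulum, inferior
frontal/orbitofrontal, precuneus, lateral temporal) sit in the middle of
the GM ribbon at 77 % of the head radius, mirrored exactly across the
mid-sagittal plane.  Template construction validates that regions stay
inside the ribbon and never overlap each other or the ventricles.

**MRI** renders T1-like tissue means (CSF 25, GM 80, WM 110) plus
additive zero-mean Gaussian noise (default sd 2).  **PET** renders uptake
means (CSF 10, WM 30, GM 70), multiplies the ten regions by a
(diagnosis, tracer) effect factor, smooths with an isotropic Gaussian of
8 mm FWHM (the resolution PET data in this setting are brought to), adds
noise, and clips at zero.  Noise is added after smoothing so the
noise-free path is analytically checkable.

Default effect factors express FDG hypometabolism deepening with stage
(AD 0.75, LMCI 0.85, EMCI 0.92, NC 1.00) and AV45 amyloid accumulation
in the reverse order (1.25 / 1.15 / 1.08 / 1.00).  These magnitudes are
free parameters of the simulation — chosen once in the range reported
for regional FDG/florbetapir differences — not estimates from any
dataset.  A second visit at ~12 months multiplies the regional signal by
a per-(diagnosis, tracer) progression factor (e.g. FDG-AD 0.88, AV45-AD
1.12); with smoothing disabled the second-visit/baseline ratio inside a
region equals the factor exactly, which is how the progression contract
is tested.  MMSE scores are drawn from [0, 30]-truncated normals whose
location is calibrated so the *truncated* mean matches the per-group,
per-visit targets (AD 22.9/20.4, EMCI 28.5/27.7, LMCI 27.6/24.4, NC
29.1/28.3); naive truncation would bias ceiling-adjacent groups ~0.3–0.5
points low.

Cohort generation is a pure function of (config, master seed): per-scan
streams are derived by stable hashing of (seed, subject, tracer,
timepoint), so any scan can be regenerated independently.

## Intensity normalization

PET volumes are rescaled by two data-derived constants: `T_max`, the
upper edge of the 10th of 50 equal-width histogram bins over the strictly
positive voxels (a pure function of the positive range, excluding
low-valued background), and `I_max`, the mean of all voxels strictly
above `T_max`.  The volume is divided by `I_max`; negative input maps to
zero.  Because `I_max` is a robust upper-level mean, a handful of
saturated hot voxels cannot compress the scale.  No hard ceiling is
applied: `I_max` necessarily lies below the bright-tissue plateau (it is
a mean over everything above threshold), so clamping at 1 would saturate
the entire cortex and destroy every intensity feature the classifiers
depend on.  The mapping is monotone, preserves grid metadata, and is
invariant to global positive rescaling to 1e-12.

## Registration

A self-contained engine estimates 6-parameter rigid (Euler rotations in
degrees + translations in mm) or 12-parameter affine (adding log-scales
and shears) world-space transforms, parameterised about the fixed
volume's centre.  Search is derivative-free Powell over a 3-level
pyramid (4×, 2×, 1× downsampling; the native level gets a light 0.7-voxel
blur to suppress interpolation artifacts).  The rigid subspace is
optimised through the whole pyramid first; the affine model then refines
all 12 parameters on the finer levels only, since scale and shear are
not resolvable on a 12³ volume.  Starting transforms are chosen between
the identity and a closed-form moments estimate (matching support
centroids and covariance ellipsoids, eigen-axes paired by the
permutation/sign combination nearest the identity) by comparing
half-resolution costs.  A final safeguard re-evaluates initial and final
parameters at native resolution and never returns a transform worse than
the initialisation.

Two similarity costs are exposed with their conventional definitions:
negative mutual information from a joint histogram over the positive
overlap, and the correlation ratio 1 − η²(F|M).  During optimisation the
correlation ratio conditions the *smoothed PET on MRI intensity bins* —
the informative direction for a sharp-anatomy/smooth-function pair — and
histogram bins shrink with pyramid level (≈ constant samples per bin),
which removed occasional catastrophic misconvergence observed with
fixed 32-bin conditioning of MRI on PET.

The benchmark simulates PET from the labelled MRI (the standard trick
when no multimodal ground truth exists), pushes it through a random pose
drawn uniformly within ±10°, ±10 mm, ±10 % scale/shear, and renders the
moving image on its own 1.2×-coarser grid — as PET scanners acquire at
lower resolution, and so that no candidate transform can resample
exactly on-grid (same-grid simulation lets the true pose reconstruct the
volume interpolation-free, biasing histogram metrics toward
slightly-wrong blurring poses).  Landmark registration error (LRE) is
the Euclidean distance between the ten ROI-centroid landmarks and the
recovered transform applied to their true-pose images.  At desk scale
(48³), rigid poses recover to ~0.3–0.9 mm (well under the 2.67 mm
voxel); affine poses are bimodal (about half sub-voxel, the rest 4–10 mm
capture failures), and the four-configuration comparison ranks
correlation-ratio/affine best, with affine ≤ rigid for each cost under
affine ground truth — the qualitative ordering expected for this
registration problem.

The atlas step registers the subject to the template affinely; the toy
cohort is generated in template space, so affine is exact there.  A
user-supplied dense deformation can be substituted where true nonrigid
warping is required; tests never depend on it.

## Parcellation and features

Analysis happens on the template grid: subject PET is resampled into
template space (by the ground-truth inverse or a recovered transform),
labels propagate by nearest-neighbour only, and the ten binary masks plus
their union are built once.  ROI voxel intensities are gathered in
ascending linear-index order — an arbitrary but fixed convention that
makes column c of the feature matrix mean "voxel-rank r of region i" for
every subject.

The feature matrix X is subjects × D with D = Σᵢ maxⱼ |k_ij|: each
region block is zero-padded to the cohort-wide maximum length of that
region.  Zero is the post-normalization background value, so padding is
indistinguishable from empty space.  Mean-centering is fold-aware (fit
on training rows only) to avoid leaking held-out information; a global
variant exists behind the same function.  Longitudinal fusion
concatenates the two visits row-wise, doubling D when both visits share
a variant.  A whole-brain variant uses every voxel non-zero in at least
one subject.

## Classifiers and evaluation

Four classifier specifications wrap scikit-learn estimators: linear SVM,
RBF SVM (defaults C = 1, γ = 0.1), linear SVM on PCA scores retaining
95 % of variance, and a random forest with t = 60 trees and √D features
per split (the conventional classification default; a flag restores
f = D).  The RBF grid search repeats random 10-subject holdouts (100
repeats at desk scale; configurable) and breaks accuracy ties toward
smaller C, then smaller γ.  The PCA sweep walks retained variance from
70 % to 99 % in 1 % steps and returns 0.95 when the profile is flat.

Pairwise experiments use stratified 10-fold cross-validation with
pooled-fold metrics; the positive class for sensitivity is always the
more impaired diagnosis.  AUC is computed by the rank (pairwise
probability) formula and verified against the threshold-sweep curve to
1e-10.  McNemar's comparison uses the exact two-sided binomial tail
below 25 discordant pairs and the continuity-corrected χ² above.

The chance-level check trains on a zero-effect phantom and evaluates on
a held-out set: with identically distributed classes, held-out accuracy
is exactly Binomial(n, ½) whatever the model, so the 95 % binomial band
is the correct reference.  (Cross-validated accuracy is *not* binomial —
fold correlations inflate its variance roughly 1.7× here — so the null
check deliberately avoids it.)

## Problem sizes and what the tests show

Desk-scale runs use 32³ phantoms (4 mm) for cohort/classification work
and 48³ (2.67 mm) for registration, with cohorts of 12–60 per group —
sizes chosen so the full suite and the acceptance script each complete
comfortably on a single CPU.  Passing tests demonstrate that the
pipeline's machinery is correct and that its qualitative behaviours
(effect ordering, registration ranking, longitudinal gain, chance-level
nulls) emerge under the stated simulation conditions.  They do not
establish clinical performance: the phantom has no inter-subject
anatomical variability, no partial-volume or scatter physics beyond
Gaussian smoothing, spherical-harmonic-free geometry, and effect sizes
that are assumptions, not measurements.  Classification accuracies on
strong-effect phantoms (≈1.0) are therefore ceiling behaviours of a
clean simulation, not predictions for clinical data.

## Known limitations

- Affine pose capture fails (4–10 mm) for roughly half of the sampled
  ±10 % scale/shear misalignments; failures are visible in the benchmark
  tables rather than silent.
- The nonrigid atlas step is approximated by affine registration, exact
  only because subjects share the template's anatomy.
- The whole-brain variant stores dense matrices; cohorts beyond a few
  hundred subjects at 2 mm would need chunking.
- `progression` is a single multiplicative factor per (diagnosis,
  tracer); real longitudinal trajectories are heterogeneous.
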