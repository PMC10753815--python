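# Methods

This note documents the models, conventions and numerical choices behind
`sctss`, in the order the pipeline runs them.

## Phantom geometry and atlas

The phantom head is an ellipsoid on a 64×64×64 grid at 3 mm isotropic
spacing (fractional semi-axes 0.40/0.46/0.42 of the grid extent; left–right,
anterior–posterior, inferior–superior). A concentric ellipsoid at 55% of
the brain semi-axes models the deep, perforator-supplied territory; the
shell outside it is the cortical-branch territory. Each depth class splits
into hemispheres and anterior/middle/posterior thirds, giving 12 labeled
regions (ACA/MCA/PCA-like cortical territories and three perforating zones
per side). A boolean *artifact-prone zone* marks the cortical rim of the
lowest quarter of slices, standing in for the skull-base regions where
susceptibility artifacts concentrate. The grid is mirror-symmetric about
the mid-sagittal plane, so the mirrored intensity used by the symmetry
feature is an exact axis flip; on real data it would be interpolated.

Lesions are spheres. On a 3 mm grid a sphere's measured diameter (maximum
pairwise voxel-center distance) is quantized in 6 mm steps, so generated
diameters avoid the band around the 1.5 cm size boundary: "small" plans
draw from 0.6–1.2 cm and "large" plans from ≥ 1.8 cm. This guarantees that
the size class measured from the voxelized mask agrees with the planned
class. Lesion placement requires the whole sphere inside the brain, its
center inside the planned territory, a margin inside the planned depth
class (distance transform ≥ half the radius), and a one-voxel gap from
previously placed lesions so planned lesions remain distinct
26-connectivity components. A plan that cannot be placed raises an error
rather than silently shrinking.

Signal model: parenchyma DWI 100, ADC 800 (arbitrary units), lesions
+40 DWI / −300 ADC, Gaussian noise (SD 2 and 20) inside the brain only.
These contrasts put lesion voxels ≈ 20 robust SDs above the DWI mode and
≈ 10 below the ADC mode — unambiguous acute-infarct contrast. Artifacts:
*symmetric pairs* add identical increments at mirror-image sites
(+40 DWI, −180 ADC, i.e. plausibly infarct-like on both criteria) entirely
inside the artifact-prone zone; *shine-through* regions add +40 DWI and
+300 ADC anywhere in cortex. Default: one of each per phantom.

## Synthetic cohorts

Clinical features are drawn per subtype from config-exposed distributions
(YAML-serializable; `default_generator_params()`). The directions follow
the clinical literature: D-dimer lognormal with median ≈ 20 µg/mL in
Trousseau syndrome versus ≈ 1.2 elsewhere, treated malignancy p = 0.95 in
TRO versus 0.01 background; aortic-arch calcification mass on grades 2–3
in aortogenic embolism versus grades 0–1 elsewhere; onset age ≈ 44 ± 7 y
in PFO-related embolism and dissection versus 72 ± 10 y otherwise;
intracranial/carotid stenosis p = 0.95/0.70 in large-artery
atherosclerosis; a cardiac embolic source p = 0.97 in cardioembolism.
The magnitudes are this package's declaration of a *well-separated*
cohort: defining markers present with probability 0.90–0.97 and background
flag noise at 0.01–0.02. The choice matters because the anomaly threshold
is a tail quantile of within-core kth-neighbor distances: background-flag
noise in the core classes directly inflates that tail and masks genuinely
undetermined cases. Real cohorts are noisier in exactly this way, so the
LOOCV accuracies measured here characterize the algorithm under favorable,
declared conditions — not expected clinical performance.

One global seed splits into per-case substreams keyed by case index, so a
cohort is reproducible case by case and prefixes are stable. Missingness
is off by default (complete data, as in a curated verification set) and
config-exposed per feature.

What the generator does **not** emulate: MR physics (b-values, coil
profiles, bias fields), real lesion morphology (spheres only), partial
volume effects, scanner-specific noise spectra, correlated comorbidities,
and label noise in the expert standard. Passing tests therefore certify
the machinery — not clinical accuracy.

## Preprocessing

*Peak normalization.* The in-brain histogram (256 bins over the observed
range; mode = center of the fullest bin, ties to the lower bin) defines
each modality's peak; a multiplicative factor maps it to the reference
peaks (DWI 100, ADC 800). Multiplicative mapping preserves zeros outside
the brain and makes the step scale-equivariant up to one bin width.

*Rotation.* In-plane tilt is the angle between the major principal axis of
the pooled central-third brain mask and the anterior–posterior axis,
computed from second moments and wrapped to (−45°, 45°]. The volume is
rotated by the negative estimate (linear interpolation for intensities,
nearest-neighbor for masks). A mask whose moment eigenvalue ratio is
below 1.02 is treated as rotationally degenerate: estimate 0 plus a
warning flag. Out-of-plane (3D) tilt is out of scope.

*Slice alignment.* The per-slice descriptor is brain-mask area (mm²) per
axial slice, which tracks both coverage and brain size. Alignment uses the
classic DTW recurrence (match/insert/delete, absolute-difference local
cost, no window — sequences are ~64 long), with diagonal-preferring
backtracking. The signed z offset is the median of (reference − query)
slice indices along the path. `standardize` applies peak normalization,
rotation correction, then resamples the query's z axis onto the reference
grid by averaging the query slices matched to each reference slice
(majority vote for masks). All geometric steps apply the identical
transform to DWI, ADC, brain mask and lesion mask.

## Infarct detection

Candidates: in-brain voxels with DWI z ≥ τ_d = 2.5 and ADC z ≤ −τ_a = 1.0.
z-scores use the histogram mode and a robust SD (1.4826 × median absolute
deviation about the mode), so large lesions do not drag the reference.
Exclusion: |mirrored DWI difference| < 15 intensity units **and**
membership in the artifact-prone zone. Both thresholds are config-exposed;
the symmetry threshold sits well above the noise floor (≈ 3 SD of a
two-voxel difference) and well below lesion contrast. Shine-through needs
no special handling — its high ADC fails the candidate criterion.

Each candidate carries 14 features: normalized grid position (3), DWI
z-score, ADC value and z-score, mirrored-voxel DWI difference, 3×3×3
neighborhood mean/SD and gradient magnitude for DWI and ADC (6), and a
location prior (0 inside the artifact-prone zone, 1 elsewhere). A
`GradientBoostingClassifier` (100 trees, depth 3, learning rate 0.1,
seeded) separates infarct from non-infarct candidates; on phantoms the
main burden is rejecting isolated noise voxels that pass both thresholds
by chance, which neighborhood statistics make nearly trivial.

Lesions are 26-connectivity components. Maximum diameter is the largest
pairwise voxel-center distance (convex-hull reduction above 1500 voxels);
a singleton component reports the maximum voxel edge (0.3 cm at 3 mm).
Territory is the plurality atlas label; location class is the plurality of
cortical/perforating membership. Lesion-unit evaluation matches predicted
to truth lesions on ≥ 1 shared voxel with at most one truth lesion per
prediction, using maximum bipartite matching so the count of matches is
the true optimum; recall = matched/truth, match rate =
matched/(matched + unmatched truth + unmatched predictions).

## Subtype classifier

Feature encoding: binaries to {0, 1}; the calcification grade ordinal on
[0, 1] (grade/3); D-dimer and age min–max scaled on the training set (a
query outside the training range scales beyond [0, 1] on purpose — extreme
values should look far away). Distance = mean absolute difference over the
features observed in the case's declared missing pattern.

The kNN training set contains only the four core subtypes; Trousseau cases
are handled by the rule layer and the undetermined group by anomaly
routing. Rule order is Trousseau first: the rule encodes a near-sufficient
clinical criterion (treated malignancy + D-dimer ≥ 5 µg/mL, both observed)
and must be able to override a kNN vote. The kNN vote (k = 5) breaks ties
by smaller mean neighbor distance, then by the fixed order SVO, BAD, LAS,
CE. The anomaly threshold per missing pattern is the 0.95 quantile of each
training point's leave-self-out kth-neighbor distance. In fine mode an
anomaly-routed case resolves to aortogenic embolism if the calcification
grade is ≥ 2, dissection if age < 55 y, otherwise Other; PFO-related
embolism is never auto-assigned, since its diagnosis requires
transesophageal echocardiography that the feature set cannot see. The
D-dimer cutoff, quantile, k, and the resolver cutoffs are config-exposed
defaults, not claims about the original clinical system.

The model bank is serialized to a single versioned JSON file; reloading
reproduces predictions exactly.

## Evaluation

LOOCV refits the complete bank for each held-out case (the fit is
vectorized; 231 folds run in ~1 s). Metrics use the standard per-class
formulas with the reporting conventions of the reference tables: half-up
rounding, integer percent for sensitivity/precision, two decimals for F,
one decimal percent for accuracy; precision and F are reported absent for
a class never predicted. `coarse_from_fine` group-sums a fine matrix and
conserves the total by construction.

The packaged reference tables (data/table2–7.csv) transcribe the printed
matching tables and metric rows of the original two-cohort evaluation.
One known defect is preserved: the cohort-2 matrix (table6) sums to 150
cases while its count columns (table7) sum to 151 — one SVO/BAD case is
missing from the printed matrix. Cohort-2 metrics are therefore computed
from the count columns, and `reproduce-tables` reports the discrepancy
instead of hiding it.

## Problem sizes and determinism

Default scales, chosen to keep a full run comfortably interactive on one
CPU: 231-case cohorts for classification (seconds), 64³ phantoms for
imaging (~0.3 s to render and standardize each), 100 phantoms for the
detection performance floor, 50 phantoms for artifact-exclusion soundness,
and a 12-phantom imaging stage inside the default pipeline run. Every
random draw flows from an explicit integer seed; two runs with the same
seed and configuration produce byte-identical cohorts, volumes,
predictions and manifests.

## Known limitations

- Spherical lesions and a 6-region-per-hemisphere atlas are deliberately
  minimal; territory assignment on real anatomy needs a real atlas and
  registration.
- The symmetry feature assumes the standardized grid's mid-sagittal plane
  is the anatomical midline; rotation correction must run first.
- The anomaly detector is a single global distance threshold per missing
  pattern; it cannot distinguish *which* undetermined etiology it is
  rejecting toward, and the fine-mode resolver is a two-rule heuristic.
- Performance numbers on synthetic cohorts characterize the machinery
  under the declared well-separated conditions and are not estimates of
  clinical accuracy.
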