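# sctss — Stroke Classification and Treatment Support System

`sctss` is a two-stage pipeline for etiologic (TOAST-style) classification
of acute ischemic stroke, aimed at settings where no stroke-trained
physician is available at first contact:

1. **Infarct detection** operates on paired DWI/ADC brain volumes. After
   peak-based intensity normalization, in-plane rotation correction, and
   dynamic-time-warping alignment of the slice axis to a reference, voxels
   satisfying the combined diffusion criterion (DWI z-score ≥ τ_d **and**
   ADC z-score ≤ −τ_a) become candidates. The ADC condition rejects T2
   shine-through (high on both DWI and ADC); mirror-symmetric high signal
   inside artifact-prone zones is also excluded, since real infarcts are
   asymmetric while susceptibility artifacts appear symmetrically at
   predictable locations. A gradient-boosted decision-tree ensemble
   classifies candidates on 14 features (position, intensity z-scores,
   mirrored-voxel difference, neighborhood statistics, location prior);
   positive voxels are grouped into lesions by 26-connectivity.
2. **Subtype classification** combines four image-derived features —
   size (< 1.5 cm vs ≥ 1.5 cm), culprit location (cortical vs perforating
   branch), lesion count, territory spread — with clinical features
   (intracranial/carotid stenosis, cardiac embolic source, treated
   malignancy, D-dimer, aortic-arch calcification grade, age). The decision
   flow is: a **Trousseau rule** (treated malignancy + elevated D-dimer →
   TRO); a **kNN vote** (k = 5) over the core subtypes SVO, BAD, LAS, CE
   under a mixed-type distance (min–max-scaled numeric differences, 0/1
   categorical mismatch, averaged over observed features); and **anomaly
   routing** — a case whose kth-neighbor distance exceeds the 95th
   percentile of the training set's leave-self-out kth-neighbor distances
   is routed to the undetermined group (ESUS+D). Missing-value patterns are
   served by a model bank with one model (and one calibrated threshold) per
   allowed pattern; there is no silent imputation.

Evaluation follows leave-one-out cross-validation with per-class
sensitivity `TP/(TP+FN)`, precision `TP/(TP+FP)`, F value
`2·sens·prec/(sens+prec)`, and overall accuracy `Σ TP / Σ (TP+FN)`.

Because no patient data ship with the package, a first-class synthetic
module generates labeled cohorts (subtype-conditioned clinical
distributions) and DWI/ADC phantoms (planted spherical lesions, symmetric
artifacts, shine-through regions, tilt/shift/noise perturbations) so every
stage is testable end to end. The published confusion matrices of the
original two-cohort evaluation are packaged as fixtures and serve as an
exact regression surface for the metrics engine.

## Worked example

```python
from sctss.classifier import ClassifierConfig
from sctss.evaluation import loocv, compute_metrics
from sctss.features import cohort_frame_to_vectors
from sctss.pipeline import COHORT1_MIX
from sctss.synthetic import generate_cohort
from sctss.types import FineSubtype

frame = generate_cohort(231, COHORT1_MIX, seed=1).to_frame()
vectors = cohort_frame_to_vectors(frame)
labels = [FineSubtype(v) for v in frame["true_fine"]]
cm = loocv(vectors, labels, ClassifierConfig(mode="coarse"))
report = compute_metrics(cm)
print(cm.to_frame()); print(report.to_frame().to_string(index=False))
print(f"Overall accuracy: {report.accuracy_pct}%")
```

Output:

```
         CE  LAS  SVO_BAD  TRO  ESUS_D
CE       48    0        0    0       3
LAS       0   26        0    0       3
SVO_BAD   0    0       52    0       1
TRO       0    0        0    9       0
ESUS_D    5    0        5    0      79

  class  patient_number  predicted_number  tp  sensitivity_pct  precision_pct  f_value
     CE              51                53  48               94             91     0.92
    LAS              29                26  26               90            100     0.95
SVO_BAD              53                57  52               98             91     0.95
    TRO               9                 9   9              100            100     1.00
 ESUS_D              89                86  79               89             92     0.90

Overall accuracy: 92.6%
```

Rows are the true (expert-assigned) subtypes of the simulated 231-case
cohort, columns the system's LOOCV predictions. All nine TRO cases are
caught by the Trousseau rule; most errors are exchanges between the
cardioembolic class and the pooled undetermined group (ESUS+D), the same
boundary that dominates errors in clinical practice.

The imaging path has the same surface:

```python
from sctss.detection import detect_candidates, group_lesions
from sctss.preprocess import standardize
from sctss.synthetic import generate_case_volumes

cohort = generate_cohort(4, {"SVO": 2, "CE": 2}, seed=3)
vol = generate_case_volumes(cohort.records[0], seed=7)   # SVO phantom
lesions = group_lesions(vol.lesion_mask, vol.spacing)
print(lesions[0].max_diameter_cm, lesions[0].location_class.value)
# 0.85 PERFORATING
```

## Command line

`sctss` exposes the stages as subcommands: `simulate-cohort`,
`simulate-volumes`, `preprocess`, `detect`, `fit`, `classify`, `loocv`,
`reproduce-tables`, and `run` (the full pipeline with a reproducibility
manifest). For example:

```bash
sctss simulate-cohort --n-cases 231 --seed 1 --out cohort.csv
sctss loocv --cohort cohort.csv --out-dir results/
sctss reproduce-tables     # recompute the packaged reference tables
```

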