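"""Synthetic cohorts and DWI/ADC phantoms with planted lesions and artifacts.

Clinical features are drawn from subtype-conditioned distributions chosen to
be well separated in the directions clinically reported for each etiology:
D-dimer strongly elevated (with treated malignancy) in Trousseau syndrome,
aortic-arch calcification shifted to grades 2-3 in aortogenic embolism,
markedly younger onset age in PFO-related embolism and dissection, stenosis
flags in large-artery atherosclerosis, and a cardiac embolic source in
cardioembolism. Lesion geometry follows the subtype conventions: a single
perforator-territory lesion < 1.5 cm for SVO and >= 1.5 cm for BAD,
single-territory cortical lesions for LAS, and multi-territory cortical
patterns for embolic etiologies.

Phantom volumes are rendered on the ellipsoid atlas grid: lesions are
spherical regions with elevated DWI and depressed ADC, optionally tilted,
shifted along z, and degraded with Gaussian noise; artifact injection adds
mirror-symmetric DWI-high pairs and T2-shine-through regions (high in both
DWI and ADC).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from sctss.atlas import Atlas, build_atlas, _CORTICAL_NAMES, _PERFORATING_NAMES
from sctss.types import (
    FINE_TO_COARSE,
    ClinicalRecord,
    CoarseSubtype,
    CountClass,
    FineSubtype,
    InfarctFeatureSet,
    LocationClass,
    SizeClass,
    TerritoryClass,
    VolumePair,
)

# --------------------------------------------------------------------------
# Default generator parameters (config-exposed; YAML-serializable)
# --------------------------------------------------------------------------

#: Age in years: normal (mean, sd), clipped to [20, 100].
#: D-dimer in ug/mL and NT-proBNP in pg/dL: lognormal (log_mean, log_sd).
#: aoac_probs: categorical over grades 0-3.
DEFAULT_GENERATOR_PARAMS: dict = {
    "clinical": {
        "age": {"default": [72.0, 10.0], "CE_PFO": [44.0, 7.0], "DISSEC": [44.0, 7.0]},
        "d_dimer": {"default": [0.18, 0.60], "TRO": [3.00, 0.35]},
        "malignancy_treated": {"default": 0.01, "TRO": 0.95},
        "aoac_probs": {
            "default": [0.65, 0.30, 0.05, 0.00],
            "AORTO": [0.00, 0.05, 0.35, 0.60],
        },
        "intracranial_stenosis": {"default": 0.02, "LAS": 0.95, "BAD": 0.15},
        "carotid_stenosis": {"default": 0.02, "LAS": 0.70},
        "cardiac_embolic_source": {"default": 0.02, "CE": 0.97, "CE_PFO": 0.70},
        "atrial_fibrillation": {"default": 0.05, "CE": 0.70},
        "nt_probnp": {"default": [5.30, 0.60], "CE": [7.30, 0.50]},
        # Per-feature probability that the feature is recorded missing.
        # Default 0: complete data, as in the verification setting.
        "missing_prob": {},
    },
    # Lesion plans. Diameters in cm; small lesions stay <= 1.2 and large
    # ones >= 1.8 so that the voxelized geometry (3 mm grid) lands on the
    # correct side of the 1.5 cm boundary.
    "lesions": {
        "SVO": {"count": [1], "count_probs": [1.0], "location": "perforating",
                "multi_territory": False, "diameter_cm": [0.6, 1.2]},
        "BAD": {"count": [1], "count_probs": [1.0], "location": "perforating",
                "multi_territory": False, "diameter_cm": [1.8, 3.0]},
        "LAS": {"count": [1, 2], "count_probs": [0.6, 0.4], "location": "cortical",
                "multi_territory": False, "diameter_cm": [1.8, 3.0]},
        "CE": {"count": [1, 2, 3], "count_probs": [0.4, 0.35, 0.25],
               "location": "cortical", "multi_territory": True,
               "diameter_cm": [1.8, 3.5]},
        "CE_PFO": {"count": [1, 2], "count_probs": [0.5, 0.5], "location": "cortical",
                   "multi_territory": True, "diameter_cm": [1.8, 3.0]},
        "AORTO": {"count": [1, 2], "count_probs": [0.5, 0.5], "location": "cortical",
                  "multi_territory": True, "diameter_cm": [1.8, 2.5]},
        "TRO": {"count": [2, 3, 4], "count_probs": [0.4, 0.4, 0.2],
                "location": "cortical", "multi_territory": True,
                "diameter_cm": [0.6, 1.2]},
        "DISSEC": {"count": [1], "count_probs": [1.0], "location": "cortical",
                   "multi_territory": False, "diameter_cm": [1.8, 3.0]},
        "OTHER": {"count": [1, 2], "count_probs": [0.6, 0.4], "location": "cortical",
                  "multi_territory": True, "diameter_cm": [0.6, 1.2]},
    },
}


def default_generator_params() -> dict:
    """A deep copy of the default generator parameters."""
    return copy.deepcopy(DEFAULT_GENERATOR_PARAMS)


def _per_subtype(params: dict, key: str, fine: FineSubtype):
    entry = params[key]
    return entry.get(fine.value, entry["default"])


# --------------------------------------------------------------------------
# Lesion plans
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PlannedLesion:
    location_class: LocationClass
    territory: str  # atlas territory name, e.g. "L_MCA"
    diameter_cm: float


@dataclass(frozen=True)
class ArtifactSpec:
    """One artifact region. ``center`` is a voxel index; for symmetric pairs
    the mirrored twin across the mid-sagittal plane is implied."""

    kind: str  # "symmetric_pair" | "shine_through"
    center: tuple[int, int, int]
    radius_mm: float
    dwi_delta: float
    adc_delta: float


@dataclass
class PhantomSpec:
    """Rendering parameters for one phantom DWI/ADC volume pair."""

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (3.0, 3.0, 3.0)
    dwi_parenchyma: float = 100.0
    adc_parenchyma: float = 800.0
    dwi_noise_sd: float = 2.0
    adc_noise_sd: float = 20.0
    lesion_dwi_contrast: float = 40.0
    lesion_adc_contrast: float = -300.0
    rotation_deg: float = 0.0
    z_offset: int = 0
    artifact_plan: Optional[list] = None  # None -> sample a default plan

    def __post_init__(self) -> None:
        if any(n < 16 for n in self.grid_shape):
            raise ValueError("grid too small to contain the brain phantom")


def sample_lesion_plan(
    fine: FineSubtype, params: dict, rng: np.random.Generator
) -> list[PlannedLesion]:
    """Draw a subtype-conditioned lesion plan (territories and diameters)."""
    spec = params["lesions"][fine.value]
    count = int(rng.choice(spec["count"], p=spec["count_probs"]))
    cortical = spec["location"] == "cortical"
    names = _CORTICAL_NAMES if cortical else _PERFORATING_NAMES
    loc = LocationClass.CORTICAL if cortical else LocationClass.PERFORATING
    lo, hi = spec["diameter_cm"]

    side = "L" if rng.random() < 0.5 else "R"
    if spec["multi_territory"] and count > 1:
        territories = [
            f"{('L', 'R')[rng.integers(2)]}_{names[rng.integers(len(names))]}"
            for _ in range(count)
        ]
    else:
        t = names[rng.integers(len(names))]
        territories = [f"{side}_{t}"] * count
    return [
        PlannedLesion(loc, terr, float(rng.uniform(lo, hi))) for terr in territories
    ]


def plan_to_infarct_features(plan: Sequence[PlannedLesion]) -> InfarctFeatureSet:
    """Ground-truth infarct features implied by a lesion plan."""
    if not plan:
        raise ValueError("empty lesion plan")
    largest = max(plan, key=lambda p: p.diameter_cm)
    return InfarctFeatureSet(
        size_class=SizeClass.LARGE if largest.diameter_cm >= 1.5 else SizeClass.SMALL,
        culprit_location=largest.location_class,
        count_class=CountClass.MULTIPLE if len(plan) >= 2 else CountClass.SINGLE,
        territory_class=(
            TerritoryClass.MULTIPLE
            if len({p.territory for p in plan}) >= 2
            else TerritoryClass.SINGLE
        ),
    )


# --------------------------------------------------------------------------
# Cohort generation
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CaseRecord:
    case_id: str
    clinical: ClinicalRecord
    infarct: InfarctFeatureSet
    fine: FineSubtype
    lesion_plan: tuple[PlannedLesion, ...]

    @property
    def coarse(self) -> CoarseSubtype:
        return FINE_TO_COARSE[self.fine]


@dataclass
class CohortTable:
    records: list[CaseRecord]
    seed: int
    generator_params: dict

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            c = r.clinical
            row = {
                "case_id": r.case_id,
                "age": c.age,
                "malignancy_treated": int(c.malignancy_treated),
                "d_dimer": c.d_dimer,
                "aoac_grade": c.aoac_grade,
                "intracranial_stenosis": int(c.intracranial_stenosis),
                "carotid_stenosis": int(c.carotid_stenosis),
                "cardiac_embolic_source": int(c.cardiac_embolic_source),
                "atrial_fibrillation": int(c.atrial_fibrillation),
                "nt_probnp": c.nt_probnp,
                "size_class": r.infarct.size_class.value,
                "culprit_location": r.infarct.culprit_location.value,
                "count_class": r.infarct.count_class.value,
                "territory_class": r.infarct.territory_class.value,
                "true_fine": r.fine.value,
                "true_coarse": r.coarse.value,
            }
            for name in c.missing_mask:
                if name in row:
                    row[name] = None
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _resolve_counts(
    n_cases: int, subtype_mix: dict[Union[FineSubtype, str], float]
) -> dict[FineSubtype, int]:
    mix = {FineSubtype(k): float(v) for k, v in subtype_mix.items()}
    if any(v < 0 for v in mix.values()):
        raise ValueError("subtype_mix values must be nonnegative")
    total = sum(mix.values())
    if n_cases == 0:
        return {k: 0 for k in mix}
    if all(float(v).is_integer() for v in mix.values()) and total == n_cases:
        return {k: int(v) for k, v in mix.items()}
    if abs(total - 1.0) < 1e-9:
        # proportions: largest-remainder apportionment to hit n_cases exactly
        raw = {k: v * n_cases for k, v in mix.items()}
        counts = {k: int(np.floor(v)) for k, v in raw.items()}
        short = n_cases - sum(counts.values())
        order = sorted(mix, key=lambda k: raw[k] - counts[k], reverse=True)
        for k in order[:short]:
            counts[k] += 1
        return counts
    raise ValueError(
        f"subtype_mix must be counts summing to n_cases={n_cases} or "
        f"proportions summing to 1 (got sum {total})"
    )


def _case_rng(seed: int, case_index: int) -> np.random.Generator:
    """Per-case substream: reproducible case-by-case from one global seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(case_index,)))


def _sample_clinical(
    fine: FineSubtype, params: dict, rng: np.random.Generator
) -> ClinicalRecord:
    p = params["clinical"]
    mean, sd = _per_subtype(p, "age", fine)
    age = float(np.clip(rng.normal(mean, sd), 20.0, 100.0))
    lm, ls = _per_subtype(p, "d_dimer", fine)
    d_dimer = float(rng.lognormal(lm, ls))
    aoac = int(rng.choice(4, p=np.asarray(_per_subtype(p, "aoac_probs", fine))))
    lm, ls = _per_subtype(p, "nt_probnp", fine)
    nt = float(rng.lognormal(lm, ls))
    record = dict(
        age=age,
        malignancy_treated=bool(rng.random() < _per_subtype(p, "malignancy_treated", fine)),
        d_dimer=d_dimer,
        aoac_grade=aoac,
        intracranial_stenosis=bool(rng.random() < _per_subtype(p, "intracranial_stenosis", fine)),
        carotid_stenosis=bool(rng.random() < _per_subtype(p, "carotid_stenosis", fine)),
        cardiac_embolic_source=bool(rng.random() < _per_subtype(p, "cardiac_embolic_source", fine)),
        atrial_fibrillation=bool(rng.random() < _per_subtype(p, "atrial_fibrillation", fine)),
        nt_probnp=nt,
    )
    missing = frozenset(
        name for name, prob in p.get("missing_prob", {}).items() if rng.random() < prob
    )
    return ClinicalRecord(missing_mask=missing, **record)


def generate_cohort(
    n_cases: int,
    subtype_mix: dict,
    params: Optional[dict] = None,
    seed: int = 0,
) -> CohortTable:
    """Generate a subtype-labeled synthetic cohort.

    ``subtype_mix`` maps fine subtype names to either integer counts summing
    to ``n_cases`` or proportions summing to 1. Deterministic for a fixed
    seed; each case draws from its own substream keyed by case index.
    """
    if n_cases < 0:
        raise ValueError("n_cases must be nonnegative")
    params = default_generator_params() if params is None else params
    counts = _resolve_counts(n_cases, subtype_mix)
    labels = [fine for fine in counts for _ in range(counts[fine])]
    records = []
    for i, fine in enumerate(labels):
        rng = _case_rng(seed, i)
        clinical = _sample_clinical(fine, params, rng)
        plan = tuple(sample_lesion_plan(fine, params, rng))
        records.append(
            CaseRecord(
                case_id=f"C{i + 1:04d}",
                clinical=clinical,
                infarct=plan_to_infarct_features(plan),
                fine=fine,
                lesion_plan=plan,
            )
        )
    return CohortTable(records=records, seed=seed, generator_params=params)


# --------------------------------------------------------------------------
# Phantom volume rendering
# --------------------------------------------------------------------------


def _ball_mask(atlas: Atlas, center: tuple[int, int, int], radius_mm: float) -> np.ndarray:
    grids = np.meshgrid(
        *[np.arange(n) * s for n, s in zip(atlas.shape, atlas.spacing)], indexing="ij"
    )
    c = [center[i] * atlas.spacing[i] for i in range(3)]
    d2 = sum((g - ci) ** 2 for g, ci in zip(grids, c))
    return d2 <= radius_mm**2


def _place_lesion(
    atlas: Atlas,
    planned: PlannedLesion,
    occupied: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Choose a center inside the planned territory and return the ball mask."""
    r_mm = planned.diameter_cm * 10.0 / 2.0
    try:
        label = atlas.names.index(planned.territory) + 1
    except ValueError:
        raise ValueError(f"unknown territory {planned.territory!r}") from None
    depth_mask = (
        atlas.cortical_mask
        if planned.location_class is LocationClass.CORTICAL
        else atlas.perforating_mask
    )
    from scipy import ndimage

    depth_edt = ndimage.distance_transform_edt(depth_mask, sampling=atlas.spacing)
    ok = (atlas.labels == label) & (atlas.brain_edt_mm >= r_mm) & (depth_edt >= 0.5 * r_mm)
    candidates = np.argwhere(ok)
    if candidates.size == 0:
        raise ValueError(
            f"lesion of diameter {planned.diameter_cm:.2f} cm cannot fit in "
            f"territory {planned.territory}"
        )
    # keep a one-voxel gap so separately planned lesions stay separate
    # components under 26-connectivity
    blocked = (
        ndimage.binary_dilation(occupied, structure=np.ones((3, 3, 3), bool))
        if occupied.any()
        else occupied
    )
    for _ in range(50):
        center = tuple(candidates[rng.integers(len(candidates))])
        ball = _ball_mask(atlas, center, r_mm)
        if not (ball & blocked).any():
            return ball
    raise ValueError(
        f"could not place lesion in {planned.territory} without overlap"
    )


def _rotate_inplane(arr: np.ndarray, deg: float, order: int) -> np.ndarray:
    """Rotate in the axial (x, y) plane about the grid center."""
    from scipy import ndimage

    if deg == 0.0:
        return arr
    out = ndimage.rotate(
        arr.astype(float), deg, axes=(0, 1), reshape=False, order=order, mode="constant"
    )
    return out


def _shift_z(arr: np.ndarray, k: int, fill=0):
    if k == 0:
        return arr.copy()
    out = np.full_like(arr, fill)
    if k > 0:
        out[:, :, k:] = arr[:, :, :-k]
    else:
        out[:, :, :k] = arr[:, :, -k:]
    return out


def _sample_default_artifacts(
    atlas: Atlas, spec: PhantomSpec, occupied: np.ndarray, rng: np.random.Generator
) -> list[ArtifactSpec]:
    """One symmetric high-signal pair in the artifact-prone rim plus one
    T2-shine-through region elsewhere in cortex."""
    plan: list[ArtifactSpec] = []
    radius = 6.0
    nx = atlas.shape[0]

    def _pick(candidate_idx, kind, dwi_delta, adc_delta, inside=None):
        for _ in range(30):
            if not len(candidate_idx):
                return
            center = tuple(int(c) for c in candidate_idx[rng.integers(len(candidate_idx))])
            art = ArtifactSpec(kind, center, radius, dwi_delta, adc_delta)
            masks = artifact_masks(atlas.shape, atlas.spacing, art)
            ok = all(
                m.any() and not (m & ~atlas.brain_mask).any() and not (m & occupied).any()
                and (inside is None or not (m & ~inside).any())
                for m in masks
            )
            if ok:
                plan.append(art)
                return

    # symmetric artifacts are planted entirely inside the artifact-prone
    # zone: that is where the detector's symmetry exclusion applies
    zone = atlas.artifact_zone & (atlas.brain_edt_mm >= radius * 0.8)
    _pick(
        np.argwhere(zone & (np.arange(nx) < nx // 2)[:, None, None]),
        "symmetric_pair",
        spec.lesion_dwi_contrast,
        0.6 * spec.lesion_adc_contrast,
        inside=atlas.artifact_zone,
    )
    _pick(
        np.argwhere(
            atlas.cortical_mask & ~atlas.artifact_zone & (atlas.brain_edt_mm >= radius)
        ),
        "shine_through",
        spec.lesion_dwi_contrast,
        -1.0 * spec.lesion_adc_contrast,  # ADC *high*
    )
    return plan


def artifact_masks(vol_shape, spacing, artifact: ArtifactSpec) -> list[np.ndarray]:
    """Voxel masks touched by one artifact (two for a symmetric pair)."""
    atlas = build_atlas(tuple(vol_shape), tuple(spacing))
    masks = [_ball_mask(atlas, artifact.center, artifact.radius_mm)]
    if artifact.kind == "symmetric_pair":
        x, y, z = artifact.center
        masks.append(_ball_mask(atlas, (vol_shape[0] - 1 - x, y, z), artifact.radius_mm))
    return masks


def inject_artifacts(
    vol: VolumePair, artifact_plan: Sequence[ArtifactSpec], seed: int = 0
) -> VolumePair:
    """Add planned artifacts to a volume pair.

    Symmetric pairs receive identical intensity increments at mirror-image
    sites across the mid-sagittal plane; shine-through regions are raised in
    both DWI and ADC. The ground-truth lesion mask is never modified, and an
    artifact overlapping planted lesion voxels is rejected.
    """
    if not artifact_plan:
        return vol
    out = vol.copy()
    for art in artifact_plan:
        masks = artifact_masks(vol.dwi.shape, vol.spacing, art)
        for m in masks:
            if not m.any() or (m & ~vol.brain_mask).any():
                raise ValueError(f"artifact at {art.center} extends outside the brain mask")
            if vol.lesion_mask is not None and (m & vol.lesion_mask).any():
                raise ValueError(f"artifact at {art.center} overlaps planted lesion voxels")
        if art.kind == "symmetric_pair":
            # identical increment mirrored voxel-for-voxel -> matched intensity
            delta_d = np.zeros_like(out.dwi)
            delta_a = np.zeros_like(out.adc)
            delta_d[masks[0]] = art.dwi_delta
            delta_a[masks[0]] = art.adc_delta
            delta_d = delta_d + delta_d[::-1, :, :]
            delta_a = delta_a + delta_a[::-1, :, :]
            out.dwi += delta_d
            out.adc += delta_a
        elif art.kind == "shine_through":
            out.dwi[masks[0]] += art.dwi_delta
            out.adc[masks[0]] += art.adc_delta
        else:
            raise ValueError(f"unknown artifact kind {art.kind!r}")
    out.meta.setdefault("artifacts", []).extend(
        {"kind": a.kind, "center": list(map(int, a.center)), "radius_mm": a.radius_mm}
        for a in artifact_plan
    )
    return out


def generate_case_volumes(
    case: CaseRecord | tuple[ClinicalRecord, FineSubtype],
    spec: Optional[PhantomSpec] = None,
    seed: int = 0,
    params: Optional[dict] = None,
    with_artifacts: bool = True,
) -> VolumePair:
    """Render a DWI/ADC phantom pair for one labeled case.

    Accepts either a :class:`CaseRecord` (its stored lesion plan is used) or
    a ``(ClinicalRecord, FineSubtype)`` pair, in which case a plan is drawn
    from the generator parameters. Returns a :class:`VolumePair` carrying
    the ground-truth lesion mask.
    """
    spec = PhantomSpec() if spec is None else spec
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(797,)))
    atlas = build_atlas(tuple(spec.grid_shape), tuple(spec.spacing))
    if isinstance(case, CaseRecord):
        plan = case.lesion_plan
        case_id = case.case_id
    else:
        clinical, fine = case
        params = default_generator_params() if params is None else params
        plan = tuple(sample_lesion_plan(fine, params, rng))
        case_id = f"adhoc_{fine.value}"

    lesion_mask = np.zeros(atlas.shape, dtype=bool)
    for planned in plan:
        lesion_mask |= _place_lesion(atlas, planned, lesion_mask, rng)

    dwi = np.where(atlas.brain_mask, spec.dwi_parenchyma, 0.0)
    adc = np.where(atlas.brain_mask, spec.adc_parenchyma, 0.0)
    dwi[lesion_mask] += spec.lesion_dwi_contrast
    adc[lesion_mask] += spec.lesion_adc_contrast

    brain = atlas.brain_mask.astype(float)
    lesion = lesion_mask.astype(float)
    if spec.rotation_deg:
        dwi = _rotate_inplane(dwi, spec.rotation_deg, order=1)
        adc = _rotate_inplane(adc, spec.rotation_deg, order=1)
        brain = _rotate_inplane(brain, spec.rotation_deg, order=1)
        lesion = _rotate_inplane(lesion, spec.rotation_deg, order=1)
    if spec.z_offset:
        dwi = _shift_z(dwi, spec.z_offset)
        adc = _shift_z(adc, spec.z_offset)
        brain = _shift_z(brain, spec.z_offset)
        lesion = _shift_z(lesion, spec.z_offset)
    brain_mask = brain >= 0.5
    lesion_mask = lesion >= 0.5

    if spec.dwi_noise_sd:
        dwi = dwi + rng.normal(0.0, spec.dwi_noise_sd, dwi.shape) * brain_mask
    if spec.adc_noise_sd:
        adc = adc + rng.normal(0.0, spec.adc_noise_sd, adc.shape) * brain_mask

    vol = VolumePair(
        dwi=dwi,
        adc=adc,
        spacing=tuple(spec.spacing),
        brain_mask=brain_mask,
        lesion_mask=lesion_mask,
        meta={"case_id": case_id, "rotation_deg": spec.rotation_deg, "z_offset": spec.z_offset},
    )
    if with_artifacts and spec.rotation_deg == 0 and spec.z_offset == 0:
        art_plan = spec.artifact_plan
        if art_plan is None:
            art_plan = _sample_default_artifacts(atlas, spec, lesion_mask, rng)
        vol = inject_artifacts(vol, art_plan, seed=seed)
    return vol
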