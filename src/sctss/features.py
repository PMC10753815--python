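"""Case feature derivation: lesions + clinical record -> classifier input.

Features (i)-(iv) are image-derived: infarct size (< 1.5 cm vs 1.5 cm or
larger, the boundary counting as large), culprit-lesion location (cortical
vs perforating branch), lesion count (single/multiple) and territory spread
(single/multiple). The culprit lesion is taken to be the largest one.
Features (v)-(xi) come from the clinical record: intracranial and carotid
stenosis, cardiac embolic source, treated malignancy, D-dimer, aortic-arch
calcification grade, and age.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from sctss.types import (
    CaseFeatureVector,
    ClinicalRecord,
    CountClass,
    FEATURE_NAMES,
    InfarctFeatureSet,
    Lesion,
    LocationClass,
    NoInfarctDetected,
    SizeClass,
    TerritoryClass,
)

SIZE_BOUNDARY_CM = 1.5


def derive_infarct_features(lesions: Sequence[Lesion]) -> InfarctFeatureSet:
    """Features (i)-(iv) from a detected lesion list.

    Raises :class:`NoInfarctDetected` when the list is empty — there is no
    infarct to classify.
    """
    if not lesions:
        raise NoInfarctDetected("no infarct detected: empty lesion list")
    largest = max(lesions, key=lambda l: l.max_diameter_cm)
    territories = {l.territory for l in lesions}
    return InfarctFeatureSet(
        size_class=(
            SizeClass.LARGE
            if largest.max_diameter_cm >= SIZE_BOUNDARY_CM
            else SizeClass.SMALL
        ),
        culprit_location=largest.location_class,
        count_class=CountClass.MULTIPLE if len(lesions) >= 2 else CountClass.SINGLE,
        territory_class=(
            TerritoryClass.MULTIPLE if len(territories) >= 2 else TerritoryClass.SINGLE
        ),
    )


def assemble_case_vector(
    infarct: InfarctFeatureSet, clinical: ClinicalRecord
) -> CaseFeatureVector:
    """Combine image-derived and clinical features into one case vector.

    The missing mask is carried over from the clinical record; numeric
    features keep their units.
    """
    return CaseFeatureVector(
        infarct=infarct,
        intracranial_stenosis=clinical.intracranial_stenosis,
        carotid_stenosis=clinical.carotid_stenosis,
        cardiac_embolic_source=clinical.cardiac_embolic_source,
        malignancy_treated=clinical.malignancy_treated,
        d_dimer=clinical.d_dimer,
        aoac_grade=clinical.aoac_grade,
        age=clinical.age,
        missing_mask=frozenset(clinical.missing_mask),
    )


# --------------------------------------------------------------------------
# CSV round-trip with stable column names
# --------------------------------------------------------------------------


def vector_to_row(vec: CaseFeatureVector) -> dict:
    row = {
        "size_class": vec.infarct.size_class.value,
        "culprit_location": vec.infarct.culprit_location.value,
        "count_class": vec.infarct.count_class.value,
        "territory_class": vec.infarct.territory_class.value,
        "intracranial_stenosis": int(vec.intracranial_stenosis),
        "carotid_stenosis": int(vec.carotid_stenosis),
        "cardiac_embolic_source": int(vec.cardiac_embolic_source),
        "malignancy_treated": int(vec.malignancy_treated),
        "d_dimer": vec.d_dimer,
        "aoac_grade": vec.aoac_grade,
        "age": vec.age,
    }
    for name in vec.missing_mask:
        row[name] = None
    return row


def row_to_vector(row: dict) -> CaseFeatureVector:
    """Rebuild a case vector from a CSV row; empty cells mark missing features."""

    def _missing(v) -> bool:
        return v is None or (isinstance(v, float) and pd.isna(v)) or v == ""

    missing = frozenset(n for n in FEATURE_NAMES if _missing(row.get(n)))
    imaging = {"size_class", "culprit_location", "count_class", "territory_class"}
    if missing & imaging:
        raise ValueError(f"image-derived features may not be missing: {missing & imaging}")
    infarct = InfarctFeatureSet(
        size_class=SizeClass(row["size_class"]),
        culprit_location=LocationClass(row["culprit_location"]),
        count_class=CountClass(row["count_class"]),
        territory_class=TerritoryClass(row["territory_class"]),
    )

    def _num(name, cast):
        return cast(row[name]) if name not in missing else cast(0)

    return CaseFeatureVector(
        infarct=infarct,
        intracranial_stenosis=bool(_num("intracranial_stenosis", int)),
        carotid_stenosis=bool(_num("carotid_stenosis", int)),
        cardiac_embolic_source=bool(_num("cardiac_embolic_source", int)),
        malignancy_treated=bool(_num("malignancy_treated", int)),
        d_dimer=_num("d_dimer", float),
        aoac_grade=_num("aoac_grade", int),
        age=_num("age", float) if "age" not in missing else 20.0,
        missing_mask=missing,
    )


def cohort_frame_to_vectors(frame: pd.DataFrame) -> list[CaseFeatureVector]:
    return [row_to_vector(row) for row in frame.to_dict(orient="records")]
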