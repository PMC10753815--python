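"""Core domain types shared across the pipeline stages."""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np


class FineSubtype(str, enum.Enum):
    """Nine-class etiologic stroke subtype (TOAST-style, fine grain)."""

    SVO = "SVO"
    BAD = "BAD"
    LAS = "LAS"
    CE = "CE"
    CE_PFO = "CE_PFO"
    AORTO = "AORTO"
    TRO = "TRO"
    DISSEC = "DISSEC"
    OTHER = "OTHER"


class CoarseSubtype(str, enum.Enum):
    """Five-class grouping used for acute-phase decision making.

    ESUS_D pools aortogenic embolism, PFO-related embolism, arterial
    dissection and other undetermined etiologies.
    """

    CE = "CE"
    LAS = "LAS"
    SVO_BAD = "SVO_BAD"
    TRO = "TRO"
    ESUS_D = "ESUS_D"


FINE_TO_COARSE: dict[FineSubtype, CoarseSubtype] = {
    FineSubtype.SVO: CoarseSubtype.SVO_BAD,
    FineSubtype.BAD: CoarseSubtype.SVO_BAD,
    FineSubtype.LAS: CoarseSubtype.LAS,
    FineSubtype.CE: CoarseSubtype.CE,
    FineSubtype.CE_PFO: CoarseSubtype.ESUS_D,
    FineSubtype.AORTO: CoarseSubtype.ESUS_D,
    FineSubtype.TRO: CoarseSubtype.TRO,
    FineSubtype.DISSEC: CoarseSubtype.ESUS_D,
    FineSubtype.OTHER: CoarseSubtype.ESUS_D,
}

#: Subtypes classified by the kNN stage; everything else is reached by the
#: rule layer (TRO) or anomaly routing (the ESUS+D group).
CORE_CLASSES: tuple[FineSubtype, ...] = (
    FineSubtype.SVO,
    FineSubtype.BAD,
    FineSubtype.LAS,
    FineSubtype.CE,
)


class SizeClass(str, enum.Enum):
    SMALL = "SMALL"  # max diameter < 1.5 cm
    LARGE = "LARGE"  # 1.5 cm or larger


class LocationClass(str, enum.Enum):
    CORTICAL = "CORTICAL"
    PERFORATING = "PERFORATING"


class CountClass(str, enum.Enum):
    SINGLE = "SINGLE"
    MULTIPLE = "MULTIPLE"


class TerritoryClass(str, enum.Enum):
    SINGLE = "SINGLE"
    MULTIPLE = "MULTIPLE"


#: Canonical feature names, in the order features enter the classifier
#: distance. The first four are image-derived; the rest are clinical.
FEATURE_NAMES: tuple[str, ...] = (
    "size_class",
    "culprit_location",
    "count_class",
    "territory_class",
    "intracranial_stenosis",
    "carotid_stenosis",
    "cardiac_embolic_source",
    "malignancy_treated",
    "d_dimer",
    "aoac_grade",
    "age",
)

#: Features treated as numeric in the mixed distance (min–max scaled);
#: aortic-arch calcification grade is ordinal and scaled to [0, 1] by /3.
NUMERIC_FEATURES: frozenset[str] = frozenset({"d_dimer", "aoac_grade", "age"})


@dataclass(frozen=True)
class ClinicalRecord:
    """Clinical features of one case, as recorded on admission.

    Units: age in years, D-dimer in ug/mL, NT-proBNP in pg/dL.
    ``missing_mask`` names the features observed as missing.
    """

    age: float
    malignancy_treated: bool
    d_dimer: float
    aoac_grade: int
    intracranial_stenosis: bool
    carotid_stenosis: bool
    cardiac_embolic_source: bool
    atrial_fibrillation: bool = False
    nt_probnp: Optional[float] = None
    missing_mask: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if "aoac_grade" not in self.missing_mask and self.aoac_grade not in (0, 1, 2, 3):
            raise ValueError(f"aoac_grade must be in 0-3, got {self.aoac_grade!r}")
        if "d_dimer" not in self.missing_mask and self.d_dimer < 0:
            raise ValueError(f"d_dimer must be >= 0, got {self.d_dimer!r}")
        if "age" not in self.missing_mask and self.age < 20:
            raise ValueError(f"age must be >= 20 (younger onset excluded), got {self.age!r}")


@dataclass(frozen=True)
class InfarctFeatureSet:
    """Image-derived features (i)-(iv): size, culprit location, count, territory."""

    size_class: SizeClass
    culprit_location: LocationClass
    count_class: CountClass
    territory_class: TerritoryClass


@dataclass(frozen=True)
class CaseFeatureVector:
    """The classifier's input record: infarct features (i)-(iv) plus clinical (v)-(xi)."""

    infarct: InfarctFeatureSet
    intracranial_stenosis: bool
    carotid_stenosis: bool
    cardiac_embolic_source: bool
    malignancy_treated: bool
    d_dimer: float
    aoac_grade: int
    age: float
    missing_mask: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        unknown = set(self.missing_mask) - set(FEATURE_NAMES)
        if unknown:
            raise ValueError(f"missing_mask names unknown features: {sorted(unknown)}")
        if "aoac_grade" not in self.missing_mask and self.aoac_grade not in (0, 1, 2, 3):
            raise ValueError(f"aoac_grade must be in 0-3, got {self.aoac_grade!r}")


@dataclass
class Lesion:
    """One connected infarct component (26-connectivity)."""

    voxels: np.ndarray  # (n, 3) integer voxel indices
    max_diameter_cm: float
    centroid_mm: tuple[float, float, float]
    territory: str
    location_class: LocationClass

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.shape[0])


@dataclass
class VolumePair:
    """Co-registered DWI and ADC volumes with masks and provenance metadata."""

    dwi: np.ndarray
    adc: np.ndarray
    spacing: tuple[float, float, float]  # mm per axis
    brain_mask: np.ndarray
    lesion_mask: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {self.dwi.shape, self.adc.shape, self.brain_mask.shape}
        if self.lesion_mask is not None:
            shapes.add(self.lesion_mask.shape)
        if len(shapes) != 1:
            raise ValueError(f"dwi/adc/masks must share one shape, got {shapes}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")

    def copy(self) -> "VolumePair":
        return VolumePair(
            dwi=self.dwi.copy(),
            adc=self.adc.copy(),
            spacing=self.spacing,
            brain_mask=self.brain_mask.copy(),
            lesion_mask=None if self.lesion_mask is None else self.lesion_mask.copy(),
            meta=dict(self.meta),
        )

    def with_meta(self, **entries) -> "VolumePair":
        meta = dict(self.meta)
        meta.update(entries)
        return replace(self, meta=meta)


class NoInfarctDetected(ValueError):
    """Raised when a lesion list is empty and infarct features cannot be derived."""
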