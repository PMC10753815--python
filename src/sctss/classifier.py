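"""TOAST-style stroke subtype classification.

The decision flow composes three mechanisms:

1. **Rule layer** — Trousseau differentiation: a patient treated for
   malignancy whose D-dimer is elevated above a cutoff is assigned TRO
   outright (both features must be observed).
2. **kNN stage** — k-nearest-neighbor majority vote over the four core
   subtypes (SVO, BAD, LAS, CE) under a mixed-type distance: min-max-scaled
   absolute difference for numeric features (D-dimer, age, and the ordinal
   aortic-arch calcification grade divided by 3), 0/1 mismatch for binary
   features, averaged over the observed features.
3. **Anomaly routing** — a query whose distance to its kth nearest core
   training case exceeds a threshold (a train-set quantile of leave-self-out
   kth-neighbor distances) is routed to the undetermined/other group:
   ESUS+D in coarse mode, or a small resolver in fine mode (aortogenic
   embolism when the calcification grade is high, dissection when the
   patient is young, otherwise Other; PFO-related embolism is never
   auto-assigned because it requires transesophageal echocardiography).

Missing data are handled by a model bank: one model per allowed
missing-feature pattern, each with its own scaling and its own calibrated
anomaly threshold on the reduced feature set. No silent imputation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from sctss.types import (
    CORE_CLASSES,
    FEATURE_NAMES,
    FINE_TO_COARSE,
    NUMERIC_FEATURES,
    CaseFeatureVector,
    CoarseSubtype,
    FineSubtype,
)

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class ClassifierConfig:
    """Tunable parameters of the classification flow."""

    k: int = 5
    anomaly_quantile: float = 0.95
    trousseau_d_dimer_cutoff: float = 5.0  # ug/mL
    mode: str = "coarse"  # "coarse" | "fine"
    aoac_other_grade: int = 2  # fine resolver: AORTO if grade >= this
    youth_age_cutoff: float = 55.0  # fine resolver: DISSEC if younger
    allowed_missing_patterns: tuple[frozenset[str], ...] = (
        frozenset(),
        frozenset({"d_dimer"}),
        frozenset({"aoac_grade"}),
    )

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not 0.0 < self.anomaly_quantile < 1.0:
            raise ValueError("anomaly_quantile must lie in (0, 1)")
        if self.trousseau_d_dimer_cutoff <= 0:
            raise ValueError("Trousseau D-dimer cutoff must be positive")
        if self.mode not in ("coarse", "fine"):
            raise ValueError(f"mode must be 'coarse' or 'fine', got {self.mode!r}")


# --------------------------------------------------------------------------
# Feature encoding
# --------------------------------------------------------------------------

_NUMERIC_IDX = [i for i, n in enumerate(FEATURE_NAMES) if n in NUMERIC_FEATURES]


def encode_case(case: CaseFeatureVector) -> np.ndarray:
    """Encode one case as a numeric vector in FEATURE_NAMES order.

    Binary features map to {0, 1}; the calcification grade is kept ordinal
    on [0, 1] by dividing by 3. Missing features carry NaN.
    """
    inf = case.infarct
    raw = {
        "size_class": float(inf.size_class.value == "LARGE"),
        "culprit_location": float(inf.culprit_location.value == "PERFORATING"),
        "count_class": float(inf.count_class.value == "MULTIPLE"),
        "territory_class": float(inf.territory_class.value == "MULTIPLE"),
        "intracranial_stenosis": float(case.intracranial_stenosis),
        "carotid_stenosis": float(case.carotid_stenosis),
        "cardiac_embolic_source": float(case.cardiac_embolic_source),
        "malignancy_treated": float(case.malignancy_treated),
        "d_dimer": float(case.d_dimer),
        "aoac_grade": float(case.aoac_grade) / 3.0,
        "age": float(case.age),
    }
    vec = np.array([raw[n] for n in FEATURE_NAMES], dtype=float)
    for i, n in enumerate(FEATURE_NAMES):
        if n in case.missing_mask:
            vec[i] = np.nan
    return vec


def _pattern_key(pattern: frozenset[str]) -> str:
    return ",".join(sorted(pattern)) if pattern else "<complete>"


@dataclass
class PatternModel:
    """kNN training state for one missing-feature pattern."""

    feature_names: tuple[str, ...]  # observed features, canonical order
    train: np.ndarray  # (n, f) scaled training matrix
    labels: tuple[str, ...]  # fine labels, aligned with rows
    scale_min: np.ndarray
    scale_range: np.ndarray
    anomaly_threshold: float

    def scaled(self, vec: np.ndarray) -> np.ndarray:
        return (vec - self.scale_min) / self.scale_range

    def distances(self, query_scaled: np.ndarray) -> np.ndarray:
        return np.abs(self.train - query_scaled[None, :]).mean(axis=1)


@dataclass
class ModelBank:
    """Per-missing-pattern kNN models plus the shared configuration."""

    config: ClassifierConfig
    models: dict[str, PatternModel]
    training_hash: str = ""
    seed: int = 0

    def model_for(self, case: CaseFeatureVector) -> PatternModel:
        key = _pattern_key(frozenset(case.missing_mask))
        if key not in self.models:
            raise KeyError(
                f"no model for missing-feature pattern {key!r}; "
                f"allowed: {sorted(self.models)}"
            )
        return self.models[key]

    # -- serialization ------------------------------------------------------

    def to_json(self, path) -> None:
        payload = {
            "schema_version": SCHEMA_VERSION,
            "config": {
                "k": self.config.k,
                "anomaly_quantile": self.config.anomaly_quantile,
                "trousseau_d_dimer_cutoff": self.config.trousseau_d_dimer_cutoff,
                "mode": self.config.mode,
                "aoac_other_grade": self.config.aoac_other_grade,
                "youth_age_cutoff": self.config.youth_age_cutoff,
                "allowed_missing_patterns": [
                    sorted(p) for p in self.config.allowed_missing_patterns
                ],
            },
            "training_hash": self.training_hash,
            "seed": self.seed,
            "models": {
                key: {
                    "feature_names": list(m.feature_names),
                    "train": m.train.tolist(),
                    "labels": list(m.labels),
                    "scale_min": m.scale_min.tolist(),
                    "scale_range": m.scale_range.tolist(),
                    "anomaly_threshold": m.anomaly_threshold,
                }
                for key, m in self.models.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "ModelBank":
        payload = json.loads(Path(path).read_text())
        if payload.get("schema_version") != SCHEMA_VERSION:
            raise ValueError(f"unsupported model bank schema: {payload.get('schema_version')}")
        cfg = payload["config"]
        config = ClassifierConfig(
            k=cfg["k"],
            anomaly_quantile=cfg["anomaly_quantile"],
            trousseau_d_dimer_cutoff=cfg["trousseau_d_dimer_cutoff"],
            mode=cfg["mode"],
            aoac_other_grade=cfg["aoac_other_grade"],
            youth_age_cutoff=cfg["youth_age_cutoff"],
            allowed_missing_patterns=tuple(
                frozenset(p) for p in cfg["allowed_missing_patterns"]
            ),
        )
        models = {
            key: PatternModel(
                feature_names=tuple(m["feature_names"]),
                train=np.asarray(m["train"], dtype=float),
                labels=tuple(m["labels"]),
                scale_min=np.asarray(m["scale_min"], dtype=float),
                scale_range=np.asarray(m["scale_range"], dtype=float),
                anomaly_threshold=float(m["anomaly_threshold"]),
            )
            for key, m in payload["models"].items()
        }
        return cls(
            config=config,
            models=models,
            training_hash=payload.get("training_hash", ""),
            seed=payload.get("seed", 0),
        )


# --------------------------------------------------------------------------
# Fitting
# --------------------------------------------------------------------------


def _kth_neighbor_distances(train: np.ndarray, k: int) -> np.ndarray:
    """Leave-self-out distance of every training point to its kth neighbor."""
    n = len(train)
    k_eff = min(k, n - 1)
    dist = np.abs(train[:, None, :] - train[None, :, :]).mean(axis=2)
    np.fill_diagonal(dist, np.inf)
    part = np.sort(dist, axis=1)
    return part[:, k_eff - 1]


def fit(
    cases: Sequence[CaseFeatureVector],
    labels: Sequence[Union[FineSubtype, str]],
    config: Optional[ClassifierConfig] = None,
    seed: int = 0,
) -> ModelBank:
    """Build the model bank from labeled training cases.

    Only core-class cases (SVO, BAD, LAS, CE) enter the kNN training set;
    the rule layer and anomaly routing account for the remaining subtypes.
    For every allowed missing pattern the training matrix is restricted to
    the observed features, min-max scaled per numeric feature, and the
    anomaly threshold is calibrated as the configured quantile of each
    training point's leave-self-out kth-neighbor distance.
    """
    config = ClassifierConfig() if config is None else config
    labels = [FineSubtype(l) for l in labels]
    if len(cases) != len(labels):
        raise ValueError("cases and labels must align")
    core_mask = [l in CORE_CLASSES for l in labels]
    core_labels = [l for l, m in zip(labels, core_mask) if m]
    for cls_ in CORE_CLASSES:
        if cls_ not in core_labels:
            raise ValueError(f"core class {cls_.value} absent from the training set")
    encoded = np.stack([encode_case(c) for c, m in zip(cases, core_mask) if m])
    if np.isnan(encoded).any():
        raise ValueError("training cases must be complete (no missing features)")

    models: dict[str, PatternModel] = {}
    for pattern in config.allowed_missing_patterns:
        observed = [i for i, n in enumerate(FEATURE_NAMES) if n not in pattern]
        names = tuple(FEATURE_NAMES[i] for i in observed)
        sub = encoded[:, observed]
        mins = sub.min(axis=0)
        ranges = sub.max(axis=0) - mins
        # binary/ordinal features are already on [0, 1]; only stretchable
        # numeric columns are min-max scaled, constant columns left alone
        scale_min = np.zeros(len(observed))
        scale_range = np.ones(len(observed))
        for col, feat_idx in enumerate(observed):
            if FEATURE_NAMES[feat_idx] in ("d_dimer", "age") and ranges[col] > 0:
                scale_min[col] = mins[col]
                scale_range[col] = ranges[col]
        train = (sub - scale_min) / scale_range
        kth = _kth_neighbor_distances(train, config.k)
        threshold = float(np.quantile(kth, config.anomaly_quantile))
        models[_pattern_key(pattern)] = PatternModel(
            feature_names=names,
            train=train,
            labels=tuple(l.value for l in core_labels),
            scale_min=scale_min,
            scale_range=scale_range,
            anomaly_threshold=threshold,
        )
    digest = hashlib.sha256(
        encoded.tobytes() + ",".join(l.value for l in core_labels).encode()
    ).hexdigest()[:16]
    return ModelBank(config=config, models=models, training_hash=digest, seed=seed)


# --------------------------------------------------------------------------
# Prediction
# --------------------------------------------------------------------------


def route_rules(
    case: CaseFeatureVector, config: ClassifierConfig
) -> Optional[FineSubtype]:
    """Rule layer: Trousseau differentiation.

    TRO iff treated malignancy AND observed D-dimer at or above the cutoff.
    Returns None when no rule decides.
    """
    if "malignancy_treated" in case.missing_mask or "d_dimer" in case.missing_mask:
        return None
    if case.malignancy_treated and case.d_dimer >= config.trousseau_d_dimer_cutoff:
        return FineSubtype.TRO
    return None


def knn_predict(
    case: CaseFeatureVector, bank: ModelBank
) -> tuple[FineSubtype, np.ndarray, float]:
    """kNN vote among core classes for one case.

    Returns (label, all neighbor distances sorted ascending, kth distance).
    Ties on the vote break to the class with the smaller mean neighbor
    distance, then to the fixed class order SVO, BAD, LAS, CE.
    """
    model = bank.model_for(case)
    vec = encode_case(case)
    observed = [i for i, n in enumerate(FEATURE_NAMES) if n in model.feature_names]
    query = model.scaled(vec[observed])
    if np.isnan(query).any():
        raise ValueError("case has missing features outside its declared pattern")
    dist = model.distances(query)
    order = np.argsort(dist, kind="stable")
    k = min(bank.config.k, len(dist))
    top = order[:k]
    votes: dict[str, list[float]] = {}
    for i in top:
        votes.setdefault(model.labels[i], []).append(float(dist[i]))
    best_count = max(len(v) for v in votes.values())
    tied = [c for c, v in votes.items() if len(v) == best_count]
    if len(tied) > 1:
        tied.sort(
            key=lambda c: (
                float(np.mean(votes[c])),
                [cc.value for cc in CORE_CLASSES].index(c),
            )
        )
    label = FineSubtype(tied[0])
    kth_distance = float(dist[top[-1]])
    return label, np.sort(dist), kth_distance


def anomaly_decision(kth_distance: float, bank: ModelBank, case: CaseFeatureVector) -> bool:
    """True when the query is farther from the core training cloud than the
    calibrated threshold for its missing pattern."""
    return kth_distance > bank.model_for(case).anomaly_threshold


def _resolve_other_fine(case: CaseFeatureVector, config: ClassifierConfig) -> FineSubtype:
    """Fine-mode resolver for anomaly-routed cases.

    High aortic-arch calcification suggests aortogenic embolism; young age
    suggests dissection; otherwise undetermined. PFO-related embolism is
    never assigned automatically.
    """
    if "aoac_grade" not in case.missing_mask and case.aoac_grade >= config.aoac_other_grade:
        return FineSubtype.AORTO
    if "age" not in case.missing_mask and case.age < config.youth_age_cutoff:
        return FineSubtype.DISSEC
    return FineSubtype.OTHER


def map_fine_to_coarse(fine: Union[FineSubtype, str]) -> CoarseSubtype:
    """Group the nine fine subtypes into the five acute-phase classes."""
    return FINE_TO_COARSE[FineSubtype(fine)]


def classify(
    case: CaseFeatureVector, bank: ModelBank
) -> Union[FineSubtype, CoarseSubtype]:
    """Full decision flow for one case.

    Rule layer first (Trousseau overrides any kNN vote), then the kNN vote
    with anomaly routing to the undetermined group. In coarse mode the
    result is mapped to the five-class grouping.
    """
    config = bank.config
    ruled = route_rules(case, config)
    if ruled is not None:
        fine = ruled
    else:
        label, _dists, kth = knn_predict(case, bank)
        if anomaly_decision(kth, bank, case):
            if config.mode == "coarse":
                return CoarseSubtype.ESUS_D
            fine = _resolve_other_fine(case, config)
        else:
            fine = label
    if config.mode == "coarse":
        return map_fine_to_coarse(fine)
    return fine
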