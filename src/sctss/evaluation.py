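"""LOOCV harness, confusion matrices, and per-class performance metrics.

Metric definitions, per subtype s: patient number = TP + FN (row sum),
predicted number = TP + FP (column sum), sensitivity = TP / (TP + FN),
precision = TP / (TP + FP), F value = the harmonic mean
2·sens·prec / (sens + prec), and overall accuracy = Σ TP / Σ patient
number. Reported values follow the printed-table conventions: sensitivity
and precision as integer percent (half-up), F to two decimals, accuracy to
one decimal percent; precision and F are absent for a class never
predicted (predicted number 0).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from sctss.types import CaseFeatureVector, CoarseSubtype, FineSubtype
from sctss.classifier import ClassifierConfig, classify, fit, map_fine_to_coarse


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal half-up rounding (the convention of the printed tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ConfusionMatrix:
    """Square matrix: rows = manually assigned (true) subtype, columns =
    predicted subtype, in a fixed label order."""

    label_order: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        n = len(self.label_order)
        if self.counts.shape != (n, n):
            raise ValueError(
                f"counts must be {n}x{n} for {n} labels, got {self.counts.shape}"
            )
        if (self.counts < 0).any():
            raise ValueError("confusion-matrix counts must be nonnegative")

    @classmethod
    def from_predictions(
        cls,
        truth: Sequence[str],
        predicted: Sequence[str],
        label_order: Sequence[str],
    ) -> "ConfusionMatrix":
        idx = {l: i for i, l in enumerate(label_order)}
        counts = np.zeros((len(label_order),) * 2, dtype=int)
        for t, p in zip(truth, predicted):
            counts[idx[str(t)], idx[str(p)]] += 1
        return cls(label_order=tuple(label_order), counts=counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.label_order), columns=list(self.label_order)
        )


@dataclass
class ClassMetrics:
    tp: int
    fn: int
    fp: int
    sensitivity: Optional[float]  # fraction; None if patient number 0
    precision: Optional[float]  # None if predicted number 0
    f_value: Optional[float]

    @property
    def patient_number(self) -> int:
        return self.tp + self.fn

    @property
    def predicted_number(self) -> int:
        return self.tp + self.fp

    @property
    def sensitivity_pct(self) -> Optional[int]:
        if self.sensitivity is None:
            return None
        return int(round_half_up(100.0 * self.sensitivity))

    @property
    def precision_pct(self) -> Optional[int]:
        if self.precision is None:
            return None
        return int(round_half_up(100.0 * self.precision))

    @property
    def f_value_rounded(self) -> Optional[float]:
        if self.f_value is None:
            return None
        return round_half_up(self.f_value, 2)


@dataclass
class MetricsReport:
    label_order: tuple[str, ...]
    per_class: dict[str, ClassMetrics]
    accuracy: float  # fraction

    @property
    def accuracy_pct(self) -> float:
        return round_half_up(100.0 * self.accuracy, 1)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for label in self.label_order:
            m = self.per_class[label]
            rows.append(
                {
                    "class": label,
                    "patient_number": m.patient_number,
                    "predicted_number": m.predicted_number,
                    "tp": m.tp,
                    "sensitivity_pct": m.sensitivity_pct,
                    "precision_pct": m.precision_pct,
                    "f_value": m.f_value_rounded,
                }
            )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "accuracy_pct": self.accuracy_pct,
            "accuracy": self.accuracy,
            "classes": {
                label: {
                    "tp": m.tp,
                    "fn": m.fn,
                    "fp": m.fp,
                    "patient_number": m.patient_number,
                    "predicted_number": m.predicted_number,
                    "sensitivity": m.sensitivity,
                    "precision": m.precision,
                    "f_value": m.f_value,
                    "sensitivity_pct": m.sensitivity_pct,
                    "precision_pct": m.precision_pct,
                    "f_value_rounded": m.f_value_rounded,
                }
                for label, m in self.per_class.items()
            },
        }


def _class_metrics(tp: int, patient_number: int, predicted_number: int) -> ClassMetrics:
    fn = patient_number - tp
    fp = predicted_number - tp
    if fn < 0 or fp < 0:
        raise ValueError("TP cannot exceed patient or predicted numbers")
    sens = tp / patient_number if patient_number > 0 else None
    prec = tp / predicted_number if predicted_number > 0 else None
    if sens is None or prec is None or (sens + prec) == 0:
        f = None
    else:
        f = 2.0 * sens * prec / (sens + prec)
    return ClassMetrics(tp=tp, fn=fn, fp=fp, sensitivity=sens, precision=prec, f_value=f)


def compute_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Per-class sensitivity/precision/F and overall accuracy from a matrix."""
    rows = cm.counts.sum(axis=1)
    cols = cm.counts.sum(axis=0)
    per_class = {
        label: _class_metrics(int(cm.counts[i, i]), int(rows[i]), int(cols[i]))
        for i, label in enumerate(cm.label_order)
    }
    total = int(rows.sum())
    accuracy = float(np.trace(cm.counts)) / total if total else 0.0
    return MetricsReport(label_order=cm.label_order, per_class=per_class, accuracy=accuracy)


def metrics_from_counts(
    labels: Sequence[str],
    tp: Sequence[int],
    patient_number: Sequence[int],
    predicted_number: Sequence[int],
) -> MetricsReport:
    """Metrics from per-class count columns when only those are available
    (used when a printed matrix and its count columns disagree)."""
    per_class = {
        l: _class_metrics(int(t), int(pn), int(dn))
        for l, t, pn, dn in zip(labels, tp, patient_number, predicted_number)
    }
    total = int(sum(patient_number))
    accuracy = float(sum(tp)) / total if total else 0.0
    return MetricsReport(label_order=tuple(labels), per_class=per_class, accuracy=accuracy)


def coarse_from_fine(
    cm_fine: ConfusionMatrix,
    mapping: dict[str, str],
    coarse_order: Optional[Sequence[str]] = None,
) -> ConfusionMatrix:
    """Group-sum a fine-grained matrix into coarse classes."""
    unmapped = [l for l in cm_fine.label_order if l not in mapping]
    if unmapped:
        raise ValueError(f"labels missing from the coarse mapping: {unmapped}")
    if coarse_order is None:
        seen: list[str] = []
        for l in cm_fine.label_order:
            if mapping[l] not in seen:
                seen.append(mapping[l])
        coarse_order = seen
    idx = {c: i for i, c in enumerate(coarse_order)}
    counts = np.zeros((len(coarse_order),) * 2, dtype=int)
    for i, li in enumerate(cm_fine.label_order):
        for j, lj in enumerate(cm_fine.label_order):
            counts[idx[mapping[li]], idx[mapping[lj]]] += cm_fine.counts[i, j]
    return ConfusionMatrix(label_order=tuple(coarse_order), counts=counts)


# --------------------------------------------------------------------------
# LOOCV
# --------------------------------------------------------------------------


def loocv(
    cases: Sequence[CaseFeatureVector],
    labels: Sequence[Union[FineSubtype, str]],
    config: Optional[ClassifierConfig] = None,
    label_order: Optional[Sequence[str]] = None,
) -> ConfusionMatrix:
    """Leave-one-out cross-validation of the full decision flow.

    Each case is classified by a model bank fitted on all remaining cases;
    predictions accumulate into a confusion matrix over the evaluation
    labels (coarse or fine according to the config mode).
    """
    config = ClassifierConfig() if config is None else config
    labels = [FineSubtype(l) for l in labels]
    if len(cases) < 2:
        raise ValueError("LOOCV needs at least 2 cases")
    truth: list[str] = []
    predicted: list[str] = []
    for i in range(len(cases)):
        rest_cases = [c for j, c in enumerate(cases) if j != i]
        rest_labels = [l for j, l in enumerate(labels) if j != i]
        try:
            bank = fit(rest_cases, rest_labels, config)
        except ValueError as exc:
            raise ValueError(f"LOOCV fold {i} cannot train: {exc}") from exc
        pred = classify(cases[i], bank)
        if config.mode == "coarse":
            truth.append(map_fine_to_coarse(labels[i]).value)
        else:
            truth.append(labels[i].value)
        predicted.append(pred.value)
    if label_order is None:
        label_order = (
            [c.value for c in CoarseSubtype]
            if config.mode == "coarse"
            else [f.value for f in FineSubtype]
        )
    return ConfusionMatrix.from_predictions(truth, predicted, label_order)


# --------------------------------------------------------------------------
# Report rendering
# --------------------------------------------------------------------------


def render_report(
    cm: ConfusionMatrix,
    metrics: MetricsReport,
    out_dir,
    stem: str = "report",
) -> dict[str, Path]:
    """Write the matching table and metric table as JSON, CSV and text.

    Output is bit-stable: content depends only on the inputs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    if len(cm.label_order) == 0:
        marker = out_dir / f"{stem}.empty"
        marker.write_text("empty report: 0x0 confusion matrix\n")
        return {"empty": marker}

    cm_csv = out_dir / f"{stem}_matrix.csv"
    cm.to_frame().to_csv(cm_csv)
    paths["matrix_csv"] = cm_csv

    metrics_csv = out_dir / f"{stem}_metrics.csv"
    metrics.to_frame().to_csv(metrics_csv, index=False)
    paths["metrics_csv"] = metrics_csv

    js = out_dir / f"{stem}.json"
    js.write_text(
        json.dumps(
            {
                "label_order": list(cm.label_order),
                "counts": cm.counts.tolist(),
                "metrics": metrics.to_dict(),
            },
            indent=1,
            sort_keys=True,
        )
    )
    paths["json"] = js

    lines = ["Matching table (rows: true, columns: predicted)", ""]
    lines.append(cm.to_frame().to_string())
    lines += ["", "Per-class metrics", "", metrics.to_frame().to_string(index=False)]
    lines.append("")
    lines.append(f"Overall accuracy: {metrics.accuracy_pct}%")
    txt = out_dir / f"{stem}.txt"
    txt.write_text("\n".join(lines) + "\n")
    paths["txt"] = txt
    return paths


def report_from_json(path) -> MetricsReport:
    payload = json.loads(Path(path).read_text())
    m = payload["metrics"]
    per_class = {
        label: ClassMetrics(
            tp=c["tp"], fn=c["fn"], fp=c["fp"],
            sensitivity=c["sensitivity"], precision=c["precision"], f_value=c["f_value"],
        )
        for label, c in m["classes"].items()
    }
    return MetricsReport(
        label_order=tuple(payload["label_order"]),
        per_class=per_class,
        accuracy=m["accuracy"],
    )
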