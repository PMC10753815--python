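"""Published reference tables for the two-cohort evaluation.

The packaged CSVs transcribe the printed matching tables (confusion
matrices) and per-class metric rows of the original two-cohort study:
Cohort 1 evaluated by LOOCV in the five-class coarse grouping (table2/3)
and the nine-class fine grouping (table4/5), and Cohort 2 as an
independent validation set (table6/7). They are the regression surface
for the metrics engine: recomputing sensitivity, precision, F and overall
accuracy from the raw counts must reproduce every printed value under the
declared rounding.

Known data caveat: the printed Cohort-2 matrix (table6) sums to 150 cases
while its count columns (table7) sum to 151 — one SVO/BAD case is
unaccounted for in the matrix. The count columns are treated as canonical
for Cohort-2 metrics; the matrix ships as printed.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from sctss.evaluation import (
    ConfusionMatrix,
    MetricsReport,
    compute_metrics,
    coarse_from_fine,
    metrics_from_counts,
)

#: Printed fine labels -> printed coarse labels.
PRINTED_FINE_TO_COARSE = {
    "CE": "CE",
    "CE-PFO": "ESUS+D",
    "LAS": "LAS",
    "SVO": "SVO/BAD",
    "BAD": "SVO/BAD",
    "Aorto": "ESUS+D",
    "Tro": "Tro",
    "Dissec": "ESUS+D",
    "Other": "ESUS+D",
}

COARSE_ORDER = ("CE", "LAS", "SVO/BAD", "Tro", "ESUS+D")

_MATRICES = {
    "cohort1_coarse": "table2.csv",
    "cohort1_fine": "table4.csv",
    "cohort2_coarse": "table6.csv",
}
_METRIC_ROWS = {
    "cohort1_coarse": "table3.csv",
    "cohort1_fine": "table5.csv",
    "cohort2_coarse": "table7.csv",
}


def _read(name: str) -> pd.DataFrame:
    with resources.files("sctss.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_matrix(key: str) -> ConfusionMatrix:
    """Load a printed matching table as a :class:`ConfusionMatrix`."""
    frame = _read(_MATRICES[key]).set_index("true")
    return ConfusionMatrix(
        label_order=tuple(frame.columns), counts=frame.to_numpy(dtype=int)
    )


def load_metric_rows(key: str) -> pd.DataFrame:
    """Load the printed per-class metric rows (counts and rounded metrics)."""
    return _read(_METRIC_ROWS[key])


def printed_accuracy_pct(key: str) -> float:
    """Overall accuracy implied by the printed count columns, 1 dp percent."""
    rows = load_metric_rows(key)
    report = metrics_from_counts(
        rows["class"], rows["tp"], rows["patient_number"], rows["predicted_number"]
    )
    return report.accuracy_pct


def _compare_report(report: MetricsReport, rows: pd.DataFrame) -> list[str]:
    """Mismatches between a recomputed report and printed metric rows."""
    problems: list[str] = []
    for row in rows.to_dict(orient="records"):
        label = row["class"]
        m = report.per_class[label]
        checks = [
            ("patient_number", m.patient_number, int(row["patient_number"])),
            ("predicted_number", m.predicted_number, int(row["predicted_number"])),
            ("tp", m.tp, int(row["tp"])),
            ("sensitivity_pct", m.sensitivity_pct, int(row["sensitivity_pct"])),
        ]
        for name, got, want in checks:
            if got != want:
                problems.append(f"{label}.{name}: computed {got} != printed {want}")
        for name, got in (
            ("precision_pct", m.precision_pct),
            ("f_value", m.f_value_rounded),
        ):
            want = row[name]
            if pd.isna(want):
                if got is not None:
                    problems.append(f"{label}.{name}: computed {got}, printed absent")
            else:
                want = int(want) if name == "precision_pct" else float(want)
                if got != want:
                    problems.append(f"{label}.{name}: computed {got} != printed {want}")
    return problems


def reproduce_tables() -> dict:
    """Recompute every derived cell of the printed tables from raw counts.

    Returns a dict with per-table mismatch lists (all empty on success), the
    recomputed accuracies, and an overall ``ok`` flag. Cohort 2 is checked
    from the table7 count columns (see module docstring); the table6 matrix
    consistency failure is reported separately as ``cohort2_matrix_caveat``.
    """
    out: dict = {"mismatches": {}, "accuracy_pct": {}}

    cm1 = load_matrix("cohort1_coarse")
    rep1 = compute_metrics(cm1)
    out["mismatches"]["cohort1_coarse"] = _compare_report(rep1, load_metric_rows("cohort1_coarse"))
    out["accuracy_pct"]["cohort1_coarse"] = rep1.accuracy_pct

    cm4 = load_matrix("cohort1_fine")
    rep4 = compute_metrics(cm4)
    out["mismatches"]["cohort1_fine"] = _compare_report(rep4, load_metric_rows("cohort1_fine"))
    out["accuracy_pct"]["cohort1_fine"] = rep4.accuracy_pct

    rows7 = load_metric_rows("cohort2_coarse")
    rep7 = metrics_from_counts(
        rows7["class"], rows7["tp"], rows7["patient_number"], rows7["predicted_number"]
    )
    out["mismatches"]["cohort2_coarse"] = _compare_report(rep7, rows7)
    out["accuracy_pct"]["cohort2_coarse"] = rep7.accuracy_pct

    grouped = coarse_from_fine(cm4, PRINTED_FINE_TO_COARSE, coarse_order=COARSE_ORDER)
    group_problems = []
    if grouped.total != cm1.total:
        group_problems.append(
            f"grouped fine matrix total {grouped.total} != coarse total {cm1.total}"
        )
    if (grouped.counts != cm1.counts).any():
        group_problems.append("grouped fine matrix differs from the printed coarse matrix")
    out["mismatches"]["fine_vs_coarse_grouping"] = group_problems

    cm6 = load_matrix("cohort2_coarse")
    out["cohort2_matrix_caveat"] = (
        f"printed cohort-2 matrix sums to {cm6.total}; count columns sum to "
        f"{int(rows7['patient_number'].sum())} (metrics use the count columns)"
    )
    out["ok"] = all(not v for v in out["mismatches"].values())
    return out
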