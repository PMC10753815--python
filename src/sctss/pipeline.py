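"""End-to-end pipeline: simulate -> preprocess -> detect -> featurize ->
fit/classify -> evaluate, with a reproducibility manifest.

The imaging stages run on a configurable subset of the cohort (rendering a
phantom volume per case is the expensive step); classification and LOOCV
always run on the full cohort table. Every run writes its fully resolved
configuration and a manifest with content hashes next to its outputs.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

import sctss
from sctss.classifier import ClassifierConfig, classify, fit
from sctss.detection import (
    detect_candidates,
    evaluate_lesion_detection,
    group_lesions,
    predict_infarct_mask,
    train_voxel_classifier,
)
from sctss.evaluation import compute_metrics, loocv, render_report
from sctss.features import cohort_frame_to_vectors
from sctss.preprocess import standardize
from sctss.synthetic import PhantomSpec, generate_case_volumes, generate_cohort
from sctss.types import FineSubtype

#: Cohort-1 subtype composition, the default simulated mix.
COHORT1_MIX = {
    "SVO": 25, "BAD": 28, "LAS": 29, "CE": 51, "CE_PFO": 7,
    "AORTO": 40, "TRO": 9, "DISSEC": 15, "OTHER": 27,
}

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "out_dir": "sctss_run",
    "mode": "coarse",
    "cohort": {
        "n_cases": 231,
        "subtype_mix": dict(COHORT1_MIX),
    },
    "volumes": {
        "enabled": True,
        "n_cases": 12,  # cases rendered through the full imaging path
        "n_train": 6,  # of which used to train the voxel classifier
        "grid_shape": [64, 64, 64],
        "spacing": [3.0, 3.0, 3.0],
    },
    "detection": {
        "tau_dwi": 2.5,
        "tau_adc": 1.0,
        "symmetry_threshold": 15.0,
    },
    "classifier": {
        "k": 5,
        "anomaly_quantile": 0.95,
        "trousseau_d_dimer_cutoff": 5.0,
        "aoac_other_grade": 2,
        "youth_age_cutoff": 55.0,
    },
}


def _merge_validate(defaults: dict, overrides: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, value in overrides.items():
        where = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ValueError(f"unknown configuration key: {where}")
        if isinstance(defaults[key], dict) and key != "subtype_mix":
            if not isinstance(value, dict):
                raise ValueError(f"configuration section {where} must be a mapping")
            out[key] = _merge_validate(defaults[key], value, where)
        else:
            out[key] = value
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Resolve a run configuration; unknown keys are rejected by name."""
    cfg = {}
    if path is not None:
        cfg = yaml.safe_load(Path(path).read_text()) or {}
    if overrides:
        cfg = _merge_validate(cfg, overrides) if cfg else dict(overrides)
    return _merge_validate(DEFAULT_CONFIG, cfg)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _classifier_config(cfg: dict) -> ClassifierConfig:
    c = cfg["classifier"]
    return ClassifierConfig(
        k=c["k"],
        anomaly_quantile=c["anomaly_quantile"],
        trousseau_d_dimer_cutoff=c["trousseau_d_dimer_cutoff"],
        mode=cfg["mode"],
        aoac_other_grade=c["aoac_other_grade"],
        youth_age_cutoff=c["youth_age_cutoff"],
    )


def run_pipeline(cfg: dict) -> dict:
    """Execute the full pipeline described by a resolved configuration.

    Returns a manifest dict (also written to ``manifest.json``). Stage
    failures raise with the failing stage named; outputs written before the
    failure remain on disk.
    """
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest: dict = {
        "package_version": sctss.__version__,
        "seed": seed,
        "stages": {},
    }
    (out_dir / "config_resolved.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))

    class _Stage:
        """Run one named stage; failures abort with the stage named."""

        def __init__(self, name):
            self.name = name

        def __enter__(self):
            return self

        def record(self, result):
            manifest["stages"][self.name] = result

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"pipeline stage '{self.name}' failed: {exc}") from exc
            return False

    with _Stage("simulate_cohort") as st:
        cohort = generate_cohort(
            cfg["cohort"]["n_cases"], cfg["cohort"]["subtype_mix"], seed=seed
        )
        path = out_dir / "cohort.csv"
        cohort.to_csv(path)
        st.record({"path": str(path), "n_cases": len(cohort), "sha256": _sha256(path)})

    if cfg["volumes"]["enabled"] and len(cohort):
        with _Stage("imaging") as st:
            v = cfg["volumes"]
            spec = PhantomSpec(
                grid_shape=tuple(v["grid_shape"]), spacing=tuple(v["spacing"])
            )
            n = min(v["n_cases"], len(cohort))
            n_train = min(v["n_train"], max(n - 1, 1))
            # spread the imaging subset across subtypes
            order = np.argsort([r.fine.value for r in cohort.records], kind="stable")
            step = max(1, len(cohort) // n)
            chosen = [cohort.records[i] for i in sorted(order[::step][:n])]
            reference = generate_case_volumes(
                chosen[0], spec=spec, seed=seed, with_artifacts=False
            )
            det = cfg["detection"]
            vols = []
            for j, rec in enumerate(chosen):
                vol = generate_case_volumes(rec, spec=spec, seed=seed + 1 + j)
                vols.append((rec, standardize(vol, reference)))
            X, y = [], []
            for rec, vol in vols[:n_train]:
                cands = detect_candidates(
                    vol, det["tau_dwi"], det["tau_adc"], det["symmetry_threshold"]
                )
                truth = vol.lesion_mask[
                    cands.indices[:, 0], cands.indices[:, 1], cands.indices[:, 2]
                ]
                X.append(cands.features)
                y.append(truth)
            model = train_voxel_classifier(np.vstack(X), np.concatenate(y), seed=seed)
            model.save(out_dir / "voxel_model.joblib")
            recalls, match_rates = [], []
            for rec, vol in vols[n_train:]:
                mask = predict_infarct_mask(
                    vol, model,
                    tau_dwi=det["tau_dwi"], tau_adc=det["tau_adc"],
                    symmetry_threshold=det["symmetry_threshold"],
                )
                pred = group_lesions(mask, vol.spacing)
                truth = group_lesions(vol.lesion_mask, vol.spacing)
                rep = evaluate_lesion_detection(pred, truth, mask.shape)
                recalls.append(rep.recall)
                match_rates.append(rep.match_rate)
            st.record({
                "n_rendered": n,
                "n_train": n_train,
                "lesion_recall": float(np.mean(recalls)) if recalls else None,
                "lesion_match_rate": float(np.mean(match_rates)) if match_rates else None,
            })

    with _Stage("fit") as st:
        frame = cohort.to_frame()
        vectors = cohort_frame_to_vectors(frame)
        labels = [FineSubtype(v) for v in frame["true_fine"]]
        bank = fit(vectors, labels, _classifier_config(cfg), seed=seed)
        path = out_dir / "bank.json"
        bank.to_json(path)
        st.record({"path": str(path), "sha256": _sha256(path)})

    with _Stage("classify") as st:
        preds = [classify(v, bank).value for v in vectors]
        frame = cohort.to_frame()
        frame["predicted"] = preds
        path = out_dir / "predictions.csv"
        frame[["case_id", "true_fine", "true_coarse", "predicted"]].to_csv(
            path, index=False
        )
        st.record({"path": str(path), "sha256": _sha256(path)})

    with _Stage("loocv") as st:
        cm = loocv(vectors, labels, _classifier_config(cfg))
        metrics = compute_metrics(cm)
        render_report(cm, metrics, out_dir, stem="loocv")
        st.record({
            "accuracy": metrics.accuracy,
            "accuracy_pct": metrics.accuracy_pct,
            "report_sha256": _sha256(out_dir / "loocv.json"),
        })

    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
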