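"""Shared fixtures: synthetic cohorts, phantom volumes, trained models.

Everything is generated programmatically and seeded; session scope keeps
the expensive phantom renders shared across tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from sctss.classifier import ClassifierConfig, fit
from sctss.detection import detect_candidates, train_voxel_classifier
from sctss.features import cohort_frame_to_vectors
from sctss.pipeline import COHORT1_MIX
from sctss.preprocess import standardize
from sctss.synthetic import generate_case_volumes, generate_cohort
from sctss.types import FineSubtype

CORE_MIX = {"SVO": 6, "BAD": 6, "LAS": 6, "CE": 8}


@pytest.fixture(scope="session")
def cohort231():
    """A full-size synthetic cohort with the reference subtype mix."""
    return generate_cohort(231, COHORT1_MIX, seed=1)


@pytest.fixture(scope="session")
def cohort231_vectors(cohort231):
    frame = cohort231.to_frame()
    vectors = cohort_frame_to_vectors(frame)
    labels = [FineSubtype(v) for v in frame["true_fine"]]
    return vectors, labels


@pytest.fixture(scope="session")
def bank231(cohort231_vectors):
    vectors, labels = cohort231_vectors
    return fit(vectors, labels, ClassifierConfig(mode="coarse"))


@pytest.fixture(scope="session")
def core_cohort():
    """A small cohort containing only the four kNN core subtypes."""
    return generate_cohort(sum(CORE_MIX.values()), CORE_MIX, seed=7)


@pytest.fixture(scope="session")
def reference_volume(core_cohort):
    """A clean (artifact-free) phantom used as the standardization target."""
    return generate_case_volumes(core_cohort.records[0], seed=0, with_artifacts=False)


@pytest.fixture(scope="session")
def svo_volume(core_cohort):
    """An SVO phantom with default artifacts, ground truth attached."""
    rec = next(r for r in core_cohort.records if r.fine is FineSubtype.SVO)
    return generate_case_volumes(rec, seed=13)


@pytest.fixture(scope="session")
def standardized_volumes(core_cohort, reference_volume):
    """Twelve standardized phantoms spanning the core subtypes."""
    out = []
    for i, rec in enumerate(core_cohort.records[:12]):
        vol = generate_case_volumes(rec, seed=200 + i)
        out.append((rec, standardize(vol, reference_volume)))
    return out


@pytest.fixture(scope="session")
def voxel_model(standardized_volumes):
    """Voxel classifier trained on half of the standardized phantoms."""
    X, y = [], []
    for _rec, vol in standardized_volumes[:6]:
        cands = detect_candidates(vol)
        X.append(cands.features)
        y.append(
            vol.lesion_mask[cands.indices[:, 0], cands.indices[:, 1], cands.indices[:, 2]]
        )
    return train_voxel_classifier(np.vstack(X), np.concatenate(y), seed=0)
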