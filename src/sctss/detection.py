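"""Infarct detection on standardized DWI/ADC pairs.

Candidate voxels satisfy the combined diffusion criterion — DWI z-score
high AND ADC z-score low — which by construction rejects T2 shine-through
(high on both DWI and ADC). Mirror-symmetric high signal inside the
artifact-prone atlas zones is also excluded, reflecting that true infarcts
are asymmetric while susceptibility artifacts occur symmetrically at
predictable locations. Surviving candidates carry a 14-dimensional feature
vector (position, intensity z-scores, symmetry, neighborhood statistics,
location prior) and are classified infarct/non-infarct by a
gradient-boosted decision-tree ensemble. Positive voxels are grouped into
lesions by 26-connectivity and evaluated lesion-by-lesion against ground
truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import joblib
import numpy as np
from scipy import ndimage
from scipy.spatial.distance import pdist
from sklearn.ensemble import GradientBoostingClassifier

from sctss.atlas import Atlas, build_atlas
from sctss.preprocess import histogram_mode
from sctss.types import Lesion, LocationClass, VolumePair

#: Default candidate thresholds (z-scores) and the symmetry threshold
#: (intensity units) below which a mirrored difference counts as symmetric.
TAU_DWI = 2.5
TAU_ADC = 1.0
SYMMETRY_THRESHOLD = 15.0

FEATURE_LABELS = (
    "pos_x", "pos_y", "pos_z",
    "dwi_z", "adc_value", "adc_z",
    "mirror_dwi_diff",
    "dwi_nbhd_mean", "dwi_nbhd_sd", "dwi_grad_mag",
    "adc_nbhd_mean", "adc_nbhd_sd", "adc_grad_mag",
    "location_prior",
)

_26 = np.ones((3, 3, 3), dtype=bool)


def robust_reference(values: np.ndarray) -> tuple[float, float]:
    """Parenchyma reference: histogram mode and a robust SD
    (1.4826 x median absolute deviation about the mode)."""
    mode = histogram_mode(values)
    mad = float(np.median(np.abs(values - mode)))
    return mode, max(1.4826 * mad, 1e-9)


def _neighborhood_stats(arr: np.ndarray, size: int = 3):
    mean = ndimage.uniform_filter(arr, size=size)
    sq = ndimage.uniform_filter(arr * arr, size=size)
    sd = np.sqrt(np.maximum(sq - mean * mean, 0.0))
    return mean, sd


def _gradient_magnitude(arr: np.ndarray, spacing) -> np.ndarray:
    gx, gy, gz = np.gradient(arr, *spacing)
    return np.sqrt(gx * gx + gy * gy + gz * gz)


@dataclass
class CandidateSet:
    """Threshold-passing voxels with their classifier features."""

    indices: np.ndarray  # (n, 3) voxel coordinates
    features: np.ndarray  # (n, 14)
    shape: tuple[int, int, int]

    def __len__(self) -> int:
        return len(self.indices)

    def mask(self, keep: Optional[np.ndarray] = None) -> np.ndarray:
        out = np.zeros(self.shape, dtype=bool)
        idx = self.indices if keep is None else self.indices[keep]
        if len(idx):
            out[idx[:, 0], idx[:, 1], idx[:, 2]] = True
        return out


def detect_candidates(
    vol: VolumePair,
    tau_dwi: float = TAU_DWI,
    tau_adc: float = TAU_ADC,
    symmetry_threshold: float = SYMMETRY_THRESHOLD,
    atlas: Optional[Atlas] = None,
) -> CandidateSet:
    """Select candidate infarct voxels and compute their feature vectors.

    A voxel qualifies iff it lies in the brain mask, its DWI z-score is
    >= ``tau_dwi`` and its ADC z-score is <= ``-tau_adc``. Voxels whose
    mirrored DWI difference falls below ``symmetry_threshold`` AND that lie
    in the artifact-prone atlas zone are excluded.
    """
    if vol.adc is None:
        raise ValueError("ADC volume is mandatory for candidate detection")
    if atlas is None:
        atlas = build_atlas(tuple(vol.dwi.shape), tuple(vol.spacing))
    brain = vol.brain_mask
    dwi_mode, dwi_sd = robust_reference(vol.dwi[brain])
    adc_mode, adc_sd = robust_reference(vol.adc[brain])
    dwi_z = (vol.dwi - dwi_mode) / dwi_sd
    adc_z = (vol.adc - adc_mode) / adc_sd

    # the standardized grid is mirror-symmetric about the mid-sagittal
    # plane, so the mirrored intensity is an exact axis flip
    mirror_diff = vol.dwi - vol.dwi[::-1, :, :]

    cand = brain & (dwi_z >= tau_dwi) & (adc_z <= -tau_adc)
    symmetric = np.abs(mirror_diff) < symmetry_threshold
    cand &= ~(symmetric & atlas.artifact_zone)
    idx = np.argwhere(cand)

    dmean, dsd = _neighborhood_stats(vol.dwi)
    amean, asd = _neighborhood_stats(vol.adc)
    dgrad = _gradient_magnitude(vol.dwi, vol.spacing)
    agrad = _gradient_magnitude(vol.adc, vol.spacing)
    prior = (~atlas.artifact_zone).astype(float)

    shape = np.asarray(vol.dwi.shape, dtype=float)
    x, y, z = idx.T if len(idx) else (np.array([], int),) * 3
    feats = np.column_stack([
        idx / (shape - 1) - 0.5 if len(idx) else np.empty((0, 3)),
        dwi_z[x, y, z],
        vol.adc[x, y, z],
        adc_z[x, y, z],
        mirror_diff[x, y, z],
        dmean[x, y, z], dsd[x, y, z], dgrad[x, y, z],
        amean[x, y, z], asd[x, y, z], agrad[x, y, z],
        prior[x, y, z],
    ]) if len(idx) else np.empty((0, len(FEATURE_LABELS)))
    return CandidateSet(indices=idx, features=feats, shape=vol.dwi.shape)


# --------------------------------------------------------------------------
# Voxel classifier
# --------------------------------------------------------------------------


@dataclass
class VoxelModel:
    """Gradient-boosted infarct/non-infarct voxel classifier."""

    estimator: GradientBoostingClassifier

    def predict(self, features: np.ndarray) -> np.ndarray:
        if len(features) == 0:
            return np.zeros(0, dtype=bool)
        return self.estimator.predict(features).astype(bool)

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        if len(features) == 0:
            return np.zeros(0)
        return self.estimator.predict_proba(features)[:, 1]

    def save(self, path) -> None:
        joblib.dump(self.estimator, Path(path))

    @classmethod
    def load(cls, path) -> "VoxelModel":
        return cls(estimator=joblib.load(Path(path)))


def train_voxel_classifier(
    features: np.ndarray,
    labels: np.ndarray,
    params: Optional[dict] = None,
    seed: int = 0,
) -> VoxelModel:
    """Fit the gradient-boosted voxel classifier. Deterministic per seed."""
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("training set must contain both infarct and non-infarct voxels")
    defaults = {"n_estimators": 100, "max_depth": 3, "learning_rate": 0.1}
    defaults.update(params or {})
    est = GradientBoostingClassifier(random_state=seed, **defaults)
    est.fit(features, labels.astype(int))
    return VoxelModel(estimator=est)


def predict_infarct_mask(vol: VolumePair, model: VoxelModel, **detect_kwargs) -> np.ndarray:
    cands = detect_candidates(vol, **detect_kwargs)
    keep = model.predict(cands.features)
    return cands.mask(keep)


# --------------------------------------------------------------------------
# Lesion grouping
# --------------------------------------------------------------------------


def _component_diameter_cm(coords_mm: np.ndarray, spacing) -> float:
    if len(coords_mm) == 1:
        return max(spacing) / 10.0  # singleton convention: max voxel edge
    if len(coords_mm) > 1500:
        # the diameter is attained on the convex hull; reduce first
        from scipy.spatial import ConvexHull

        hull = ConvexHull(coords_mm, qhull_options="QJ")
        coords_mm = coords_mm[hull.vertices]
    return float(pdist(coords_mm).max()) / 10.0


def group_lesions(
    infarct_mask: np.ndarray,
    spacing: tuple[float, float, float],
    atlas: Optional[Atlas] = None,
) -> list[Lesion]:
    """Connected components (26-connectivity) with physical measurements.

    Territory is the atlas label holding the plurality of lesion voxels;
    location class is the plurality of cortical/perforating membership.
    An empty mask yields an empty list.
    """
    if atlas is None:
        atlas = build_atlas(tuple(infarct_mask.shape), tuple(spacing))
    labeled, n = ndimage.label(infarct_mask, structure=_26)
    spacing_arr = np.asarray(spacing, dtype=float)
    lesions = []
    cortical_lut = np.array([False] + list(atlas.is_cortical))
    for comp in range(1, n + 1):
        voxels = np.argwhere(labeled == comp)
        coords_mm = voxels * spacing_arr
        labels_here = atlas.labels[voxels[:, 0], voxels[:, 1], voxels[:, 2]]
        labels_here = labels_here[labels_here > 0]
        if len(labels_here):
            counts = np.bincount(labels_here, minlength=len(atlas.names) + 1)
            territory_label = int(np.argmax(counts))
            territory = atlas.territory_name(territory_label)
            n_cortical = int(cortical_lut[labels_here].sum())
            location = (
                LocationClass.CORTICAL
                if n_cortical * 2 >= len(labels_here)
                else LocationClass.PERFORATING
            )
        else:  # component entirely outside the atlas (should not happen)
            territory = "unknown"
            location = LocationClass.CORTICAL
        lesions.append(
            Lesion(
                voxels=voxels,
                max_diameter_cm=_component_diameter_cm(coords_mm, spacing),
                centroid_mm=tuple(coords_mm.mean(axis=0)),
                territory=territory,
                location_class=location,
            )
        )
    return lesions


# --------------------------------------------------------------------------
# Lesion-level evaluation
# --------------------------------------------------------------------------


@dataclass
class DetectionReport:
    """Lesion-unit agreement between predicted and ground-truth lesions."""

    n_truth: int
    n_predicted: int
    n_matched: int
    recall: float
    match_rate: float
    pairs: list[tuple[int, int]]  # (predicted index, truth index)


def _overlap_matrix(predicted: Sequence[Lesion], truth: Sequence[Lesion], shape) -> np.ndarray:
    overlaps = np.zeros((len(predicted), len(truth)), dtype=int)
    truth_masks = []
    for t in truth:
        m = np.zeros(shape, dtype=bool)
        m[t.voxels[:, 0], t.voxels[:, 1], t.voxels[:, 2]] = True
        truth_masks.append(m)
    for i, p in enumerate(predicted):
        for j, m in enumerate(truth_masks):
            overlaps[i, j] = int(m[p.voxels[:, 0], p.voxels[:, 1], p.voxels[:, 2]].sum())
    return overlaps


def evaluate_lesion_detection(
    predicted: Sequence[Lesion],
    truth: Sequence[Lesion],
    shape: tuple[int, int, int],
) -> DetectionReport:
    """Match lesions on >= 1 voxel overlap, one predicted per truth lesion.

    Matching maximizes the number of matched pairs (maximum bipartite
    matching on the overlap graph). ``recall`` is the matched fraction of
    truth lesions; ``match_rate`` divides matches by matched + unmatched
    truth + unmatched predictions.
    """
    if not truth and not predicted:
        return DetectionReport(0, 0, 0, 1.0, 1.0, [])
    pairs: list[tuple[int, int]] = []
    if truth and predicted:
        from scipy.sparse import csr_matrix
        from scipy.sparse.csgraph import maximum_bipartite_matching

        overlaps = _overlap_matrix(predicted, truth, shape)
        graph = csr_matrix((overlaps > 0).astype(int))
        match = maximum_bipartite_matching(graph, perm_type="column")
        pairs = [(i, int(j)) for i, j in enumerate(match) if j >= 0]
    n_matched = len(pairs)
    n_truth, n_pred = len(truth), len(predicted)
    recall = n_matched / n_truth if n_truth else 1.0
    denom = n_matched + (n_truth - n_matched) + (n_pred - n_matched)
    match_rate = n_matched / denom if denom else 1.0
    return DetectionReport(
        n_truth=n_truth,
        n_predicted=n_pred,
        n_matched=n_matched,
        recall=recall,
        match_rate=match_rate,
        pairs=pairs,
    )
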