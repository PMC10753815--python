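"""Candidate detection, voxel classification, lesion grouping and matching."""

import itertools

import numpy as np
import pytest

from sctss.atlas import build_atlas
from sctss.detection import (
    detect_candidates,
    evaluate_lesion_detection,
    group_lesions,
    predict_infarct_mask,
    train_voxel_classifier,
    VoxelModel,
)
from sctss.synthetic import (
    ArtifactSpec,
    artifact_masks,
    generate_case_volumes,
    generate_cohort,
    inject_artifacts,
)
from sctss.types import Lesion, LocationClass, VolumePair


def _flat_volume(value_dwi=100.0, value_adc=800.0):
    atlas = build_atlas()
    dwi = np.where(atlas.brain_mask, value_dwi, 0.0)
    adc = np.where(atlas.brain_mask, value_adc, 0.0)
    return VolumePair(
        dwi=dwi, adc=adc, spacing=atlas.spacing, brain_mask=atlas.brain_mask.copy()
    )


class TestDetectCandidates:
    def test_uniform_parenchyma_yields_no_candidates(self):
        assert len(detect_candidates(_flat_volume())) == 0

    def test_noise_only_candidates_are_rare(self):
        vol = _flat_volume()
        rng = np.random.default_rng(0)
        n = int(vol.brain_mask.sum())
        vol.dwi[vol.brain_mask] += rng.normal(0, 2.0, n)
        vol.adc[vol.brain_mask] += rng.normal(0, 20.0, n)
        # joint threshold crossings from pure noise are rare and scattered
        assert len(detect_candidates(vol)) < 0.005 * n

    def test_shine_through_region_produces_no_candidates(self):
        vol = _flat_volume()
        art = ArtifactSpec("shine_through", (40, 30, 40), 8.0, 50.0, 300.0)
        out = inject_artifacts(vol, [art], seed=0)
        (m,) = artifact_masks(out.dwi.shape, out.spacing, art)
        cands = detect_candidates(out)
        assert not cands.mask()[m].any()

    def test_planted_lesion_well_covered(self, svo_volume):
        cands = detect_candidates(svo_volume)
        mask = cands.mask()
        covered = (mask & svo_volume.lesion_mask).sum() / svo_volume.lesion_mask.sum()
        assert covered >= 0.9

    def test_symmetry_feature_vanishes_on_mirror_symmetric_volume(self):
        vol = _flat_volume()
        # make an asymmetric lesion-like spot to obtain candidates, mirrored
        # exactly so the volume stays mirror-symmetric
        centers = [(18, 32, 32), (45, 32, 32)]
        for c in centers:
            ball = artifact_masks(vol.dwi.shape, vol.spacing,
                                  ArtifactSpec("shine_through", c, 6.0, 0, 0))[0]
            vol.dwi[ball] += 50.0
            vol.adc[ball] -= 300.0
        cands = detect_candidates(vol, symmetry_threshold=0.0)  # no exclusion
        assert len(cands) > 0
        mirror_col = cands.features[:, 6]
        assert np.abs(mirror_col).max() <= 1e-9

    def test_missing_adc_rejected(self, svo_volume):
        vol = svo_volume.copy()
        vol.adc = None
        with pytest.raises((ValueError, AttributeError)):
            detect_candidates(vol)

    def test_artifact_voxels_never_candidates_across_seeds(self):
        """Soundness of the exclusion rules over many generated phantoms."""
        cohort = generate_cohort(50, {"CE": 25, "LAS": 25}, seed=17)
        for i, rec in enumerate(cohort.records):
            vol = generate_case_volumes(rec, seed=3000 + i)
            arts = vol.meta.get("artifacts", [])
            cands = detect_candidates(vol)
            cmask = cands.mask()
            for art in arts:
                spec = ArtifactSpec(
                    art["kind"], tuple(art["center"]), art["radius_mm"], 0.0, 0.0
                )
                for m in artifact_masks(vol.dwi.shape, vol.spacing, spec):
                    assert not (cmask & m).any(), (rec.case_id, art)


class TestVoxelClassifier:
    def test_separable_toy_features_fit_perfectly(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.3, (20, 2)), rng.normal(3, 0.3, (20, 2))])
        y = np.array([False] * 20 + [True] * 20)
        model = train_voxel_classifier(X, y, seed=0)
        assert (model.predict(X) == y).all()

    def test_single_class_rejected(self):
        X = np.zeros((10, 2))
        with pytest.raises(ValueError, match="both"):
            train_voxel_classifier(X, np.ones(10, bool), seed=0)

    def test_serialization_round_trip(self, voxel_model, tmp_path, standardized_volumes):
        path = tmp_path / "model.joblib"
        voxel_model.save(path)
        loaded = VoxelModel.load(path)
        _rec, vol = standardized_volumes[-1]
        cands = detect_candidates(vol)
        np.testing.assert_array_equal(
            voxel_model.predict(cands.features), loaded.predict(cands.features)
        )

    def test_recall_floor_on_fresh_phantoms(self, voxel_model, standardized_volumes):
        recalls = []
        for _rec, vol in standardized_volumes[6:]:
            mask = predict_infarct_mask(vol, voxel_model)
            rep = evaluate_lesion_detection(
                group_lesions(mask, vol.spacing),
                group_lesions(vol.lesion_mask, vol.spacing),
                mask.shape,
            )
            recalls.append(rep.recall)
        assert np.mean(recalls) >= 0.8


class TestGroupLesions:
    def test_single_voxel_uses_edge_convention(self):
        mask = np.zeros((64, 64, 64), bool)
        mask[30, 30, 30] = True
        lesions = group_lesions(mask, (1.0, 1.0, 1.0))
        assert len(lesions) == 1
        assert lesions[0].max_diameter_cm == pytest.approx(0.1)

    def test_diagonal_voxels_are_one_component(self):
        mask = np.zeros((64, 64, 64), bool)
        mask[30, 30, 30] = True
        mask[31, 31, 31] = True
        lesions = group_lesions(mask, (3.0, 3.0, 3.0))
        assert len(lesions) == 1

    def test_planted_ball_diameter_recovered(self):
        atlas = build_atlas()
        ball = artifact_masks(
            atlas.shape, atlas.spacing, ArtifactSpec("shine_through", (32, 30, 32), 8.0, 0, 0)
        )[0]
        lesions = group_lesions(ball, atlas.spacing)
        assert len(lesions) == 1
        assert lesions[0].max_diameter_cm == pytest.approx(1.6, rel=0.1)

    def test_empty_mask_empty_list(self):
        assert group_lesions(np.zeros((64, 64, 64), bool), (3.0, 3.0, 3.0)) == []

    def test_territory_and_location_from_atlas(self, svo_volume):
        lesions = group_lesions(svo_volume.lesion_mask, svo_volume.spacing)
        assert len(lesions) == 1
        assert lesions[0].location_class is LocationClass.PERFORATING
        assert lesions[0].territory.split("_", 1)[1] in (
            "ant_perf", "lenticulostriate", "thalamoperf"
        )


def _toy_lesion(voxels):
    arr = np.asarray(voxels)
    return Lesion(
        voxels=arr, max_diameter_cm=0.3, centroid_mm=(0, 0, 0),
        territory="L_MCA", location_class=LocationClass.CORTICAL,
    )


def brute_force_max_matches(overlap: np.ndarray) -> int:
    """Oracle: maximum one-to-one matching by exhaustive assignment."""
    n_pred, n_truth = overlap.shape
    best = 0
    truth_idx = list(range(n_truth))
    for r in range(min(n_pred, n_truth), 0, -1):
        for preds in itertools.permutations(range(n_pred), r):
            for truths in itertools.combinations(truth_idx, r):
                for perm in itertools.permutations(truths):
                    if all(overlap[p, t] > 0 for p, t in zip(preds, perm)):
                        return r
    return best


class TestEvaluateLesionDetection:
    def test_perfect_detection(self):
        lesions = [_toy_lesion([[1, 1, 1]]), _toy_lesion([[5, 5, 5]])]
        rep = evaluate_lesion_detection(lesions, lesions, (8, 8, 8))
        assert rep.recall == 1.0 and rep.match_rate == 1.0

    def test_empty_prediction_zero_recall(self):
        rep = evaluate_lesion_detection([], [_toy_lesion([[1, 1, 1]])], (8, 8, 8))
        assert rep.recall == 0.0

    def test_false_positives_lower_match_rate_not_recall(self):
        truth = [_toy_lesion([[1, 1, 1]])]
        pred = [_toy_lesion([[1, 1, 1]]), _toy_lesion([[5, 5, 5]])]
        rep = evaluate_lesion_detection(pred, truth, (8, 8, 8))
        assert rep.recall == 1.0
        assert rep.match_rate == pytest.approx(0.5)

    def test_matching_equals_exhaustive_oracle_on_random_instances(self):
        rng = np.random.default_rng(4)
        shape = (12, 12, 12)
        for _trial in range(30):
            n_pred, n_truth = rng.integers(1, 5, 2)
            all_vox = [[int(a), int(b), int(c)] for a in range(4) for b in range(4) for c in range(4)]
            preds = [
                _toy_lesion(rng.choice(all_vox, size=rng.integers(1, 4), replace=False))
                for _ in range(n_pred)
            ]
            truths = [
                _toy_lesion(rng.choice(all_vox, size=rng.integers(1, 4), replace=False))
                for _ in range(n_truth)
            ]
            from sctss.detection import _overlap_matrix

            overlap = _overlap_matrix(preds, truths, shape)
            rep = evaluate_lesion_detection(preds, truths, shape)
            assert rep.n_matched == brute_force_max_matches(overlap)
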