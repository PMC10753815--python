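"""kNN + anomaly subtype classifier: oracle equivalence and decision flow."""

import numpy as np
import pytest

from sctss.classifier import (
    ClassifierConfig,
    ModelBank,
    anomaly_decision,
    classify,
    encode_case,
    fit,
    knn_predict,
    map_fine_to_coarse,
    route_rules,
)
from sctss.features import cohort_frame_to_vectors
from sctss.synthetic import generate_cohort
from sctss.types import (
    CaseFeatureVector,
    CoarseSubtype,
    CountClass,
    FINE_TO_COARSE,
    FineSubtype,
    InfarctFeatureSet,
    LocationClass,
    SizeClass,
    TerritoryClass,
)

CORE_MIX = {"SVO": 8, "BAD": 8, "LAS": 8, "CE": 10}


def _vec(
    size=SizeClass.SMALL, loc=LocationClass.PERFORATING,
    count=CountClass.SINGLE, terr=TerritoryClass.SINGLE,
    ic=False, car=False, ces=False, mal=False,
    d_dimer=1.0, aoac=0, age=70.0, missing=frozenset(),
):
    return CaseFeatureVector(
        infarct=InfarctFeatureSet(size, loc, count, terr),
        intracranial_stenosis=ic, carotid_stenosis=car,
        cardiac_embolic_source=ces, malignancy_treated=mal,
        d_dimer=d_dimer, aoac_grade=aoac, age=age, missing_mask=missing,
    )


@pytest.fixture(scope="module")
def core_vectors():
    frame = generate_cohort(sum(CORE_MIX.values()), CORE_MIX, seed=23).to_frame()
    return cohort_frame_to_vectors(frame), [FineSubtype(v) for v in frame["true_fine"]]


@pytest.fixture(scope="module")
def small_bank(core_vectors):
    vectors, labels = core_vectors
    return fit(vectors, labels, ClassifierConfig(mode="coarse"))


def naive_mixed_distance(a: CaseFeatureVector, b: CaseFeatureVector, mins, ranges, observed):
    """Independent oracle: the documented metric computed feature by feature."""
    enc_a, enc_b = encode_case(a), encode_case(b)
    total = 0.0
    for j, i in enumerate(observed):
        da = (enc_a[i] - mins[j]) / ranges[j]
        db = (enc_b[i] - mins[j]) / ranges[j]
        total += abs(da - db)
    return total / len(observed)


class TestFit:
    def test_bank_has_all_allowed_patterns(self, small_bank):
        assert "<complete>" in small_bank.models
        assert "d_dimer" in small_bank.models
        n_core = sum(CORE_MIX.values())
        assert small_bank.models["<complete>"].train.shape[0] == n_core

    def test_missing_pattern_model_drops_the_feature(self, small_bank):
        model = small_bank.models["d_dimer"]
        assert "d_dimer" not in model.feature_names
        assert len(model.feature_names) == 10

    def test_absent_core_class_rejected(self, core_vectors):
        vectors, labels = core_vectors
        keep = [l is not FineSubtype.LAS for l in labels]
        with pytest.raises(ValueError, match="LAS"):
            fit(
                [v for v, k in zip(vectors, keep) if k],
                [l for l, k in zip(labels, keep) if k],
                ClassifierConfig(),
            )

    def test_anomaly_threshold_matches_quadratic_oracle(self, core_vectors, small_bank):
        from scipy.spatial.distance import cdist

        model = small_bank.models["<complete>"]
        k = small_bank.config.k
        dist = cdist(model.train, model.train, metric="cityblock") / model.train.shape[1]
        np.fill_diagonal(dist, np.inf)
        kth = np.sort(dist, axis=1)[:, k - 1]
        expected = float(np.quantile(kth, small_bank.config.anomaly_quantile))
        assert model.anomaly_threshold == pytest.approx(expected)

    def test_fit_deterministic(self, core_vectors):
        vectors, labels = core_vectors
        a = fit(vectors, labels, ClassifierConfig())
        b = fit(vectors, labels, ClassifierConfig())
        np.testing.assert_array_equal(
            a.models["<complete>"].train, b.models["<complete>"].train
        )
        assert a.training_hash == b.training_hash


class TestRouteRules:
    CFG = ClassifierConfig()

    def test_treated_malignancy_with_high_d_dimer_is_trousseau(self):
        case = _vec(mal=True, d_dimer=12.0)
        assert route_rules(case, self.CFG) is FineSubtype.TRO

    def test_no_malignancy_no_decision(self):
        assert route_rules(_vec(mal=False, d_dimer=50.0), self.CFG) is None

    def test_missing_d_dimer_no_decision(self):
        case = _vec(mal=True, d_dimer=12.0, missing=frozenset({"d_dimer"}))
        assert route_rules(case, self.CFG) is None

    def test_rule_overrides_knn_vote(self, small_bank):
        # a case that looks exactly like an SVO neighbor but carries the
        # Trousseau markers must come out TRO
        case = _vec(mal=True, d_dimer=30.0)
        assert classify(case, small_bank) is CoarseSubtype.TRO


class TestKnnPredict:
    def test_query_equal_to_training_point_distance_zero(self, core_vectors):
        vectors, labels = core_vectors
        bank = fit(vectors, labels, ClassifierConfig(k=1))
        label, dists, kth = knn_predict(vectors[0], bank)
        assert kth == 0.0
        assert label is labels[0]

    def test_matches_exhaustive_oracle_on_cohort(self, core_vectors, small_bank):
        vectors, labels = core_vectors
        model = small_bank.models["<complete>"]
        observed = list(range(len(model.feature_names)))
        k = small_bank.config.k
        for query in vectors[:20]:
            dists = np.array([
                naive_mixed_distance(
                    query, train_case, model.scale_min, model.scale_range, observed
                )
                for train_case in vectors
            ])
            _, got_dists, got_kth = knn_predict(query, small_bank)
            np.testing.assert_allclose(got_dists, np.sort(dists), atol=1e-12)
            assert got_kth == pytest.approx(np.sort(dists)[k - 1])

    def test_majority_vote(self):
        # three neighbors labeled (CE, CE, LAS) at k=3 -> CE
        base = dict(ic=False, car=False, ces=False, mal=False, aoac=0)
        train = [
            _vec(age=60.0, d_dimer=1.0, ces=True),
            _vec(age=61.0, d_dimer=1.1, ces=True),
            _vec(age=60.5, d_dimer=1.0, ic=True),
            _vec(age=90.0, d_dimer=9.9),
            _vec(age=20.0, d_dimer=0.1, loc=LocationClass.CORTICAL),
        ]
        labels = [FineSubtype.CE, FineSubtype.CE, FineSubtype.LAS,
                  FineSubtype.SVO, FineSubtype.BAD]
        bank = fit(train, labels, ClassifierConfig(k=3))
        label, _, _ = knn_predict(_vec(age=60.2, d_dimer=1.05, ces=True), bank)
        assert label is FineSubtype.CE

    def test_unknown_missing_pattern_rejected(self, small_bank):
        case = _vec(missing=frozenset({"age"}))
        with pytest.raises(KeyError, match="missing-feature pattern"):
            knn_predict(case, small_bank)


class TestAnomalyDecision:
    def test_zero_distance_is_not_other(self, small_bank):
        assert anomaly_decision(0.0, small_bank, _vec()) is False

    def test_far_outlier_is_other(self, core_vectors, small_bank):
        # all binary features flipped relative to any training case and
        # numerics far outside the training range
        case = _vec(
            size=SizeClass.LARGE, loc=LocationClass.CORTICAL,
            count=CountClass.MULTIPLE, terr=TerritoryClass.MULTIPLE,
            ic=True, car=True, ces=True, mal=True, d_dimer=500.0, aoac=3, age=20.0,
        )
        _, _, kth = knn_predict(case, small_bank)
        assert anomaly_decision(kth, small_bank, case) is True

    def test_calibration_flags_about_five_percent_of_training(self, core_vectors, small_bank):
        vectors, _ = core_vectors
        k = small_bank.config.k
        threshold = small_bank.models["<complete>"].anomaly_threshold
        flagged = 0
        for v in vectors:
            _, dists, _ = knn_predict(v, small_bank)
            # the query is a training point: skip its zero self-distance to
            # get the leave-self-out kth-neighbor distance
            if dists[k] > threshold:
                flagged += 1
        assert 1 <= flagged <= 0.15 * len(vectors)


class TestClassifyFlow:
    def test_coarse_mode_maps_core_label(self, small_bank, core_vectors):
        vectors, labels = core_vectors
        out = classify(vectors[0], small_bank)
        assert isinstance(out, CoarseSubtype)

    def test_fine_mode_others_resolver(self, core_vectors):
        vectors, labels = core_vectors
        bank = fit(vectors, labels, ClassifierConfig(mode="fine"))
        aorto_like = _vec(
            size=SizeClass.LARGE, loc=LocationClass.CORTICAL,
            count=CountClass.MULTIPLE, terr=TerritoryClass.MULTIPLE,
            aoac=3, d_dimer=300.0, age=75.0, ic=True, car=True, ces=True,
        )
        assert classify(aorto_like, bank) is FineSubtype.AORTO
        young_outlier = _vec(
            size=SizeClass.LARGE, loc=LocationClass.CORTICAL,
            count=CountClass.MULTIPLE, terr=TerritoryClass.MULTIPLE,
            aoac=0, d_dimer=300.0, age=25.0, ic=True, car=True, ces=True,
        )
        assert classify(young_outlier, bank) is FineSubtype.DISSEC

    def test_ce_pfo_never_predicted(self, cohort231_vectors):
        vectors, labels = cohort231_vectors
        bank = fit(vectors, labels, ClassifierConfig(mode="fine"))
        preds = {classify(v, bank) for v in vectors}
        assert FineSubtype.CE_PFO not in preds

    def test_missing_data_uses_other_model_without_crashing(self, small_bank):
        complete = _vec(d_dimer=1.0)
        for pattern in small_bank.config.allowed_missing_patterns:
            case = _vec(missing=pattern)
            out = classify(case, small_bank)
            assert isinstance(out, CoarseSubtype)

    def test_determinism(self, small_bank, core_vectors):
        vectors, _ = core_vectors
        first = [classify(v, small_bank) for v in vectors]
        second = [classify(v, small_bank) for v in vectors]
        assert first == second


class TestCoarseMapping:
    def test_reference_fine_counts_group_to_coarse(self):
        fine_counts = {
            FineSubtype.SVO: 25, FineSubtype.BAD: 28, FineSubtype.LAS: 29,
            FineSubtype.CE: 51, FineSubtype.CE_PFO: 7, FineSubtype.AORTO: 40,
            FineSubtype.TRO: 9, FineSubtype.DISSEC: 15, FineSubtype.OTHER: 27,
        }
        coarse = {}
        for f, n in fine_counts.items():
            coarse[map_fine_to_coarse(f)] = coarse.get(map_fine_to_coarse(f), 0) + n
        assert coarse == {
            CoarseSubtype.SVO_BAD: 53, CoarseSubtype.CE: 51, CoarseSubtype.LAS: 29,
            CoarseSubtype.TRO: 9, CoarseSubtype.ESUS_D: 89,
        }

    def test_tro_maps_to_itself(self):
        assert map_fine_to_coarse(FineSubtype.TRO) is CoarseSubtype.TRO

    def test_mapping_total_and_surjective(self):
        assert set(FINE_TO_COARSE) == set(FineSubtype)
        assert set(FINE_TO_COARSE.values()) == set(CoarseSubtype)


class TestSerialization:
    def test_bank_json_round_trip(self, small_bank, core_vectors, tmp_path):
        vectors, _ = core_vectors
        path = tmp_path / "bank.json"
        small_bank.to_json(path)
        loaded = ModelBank.from_json(path)
        for v in vectors[:10]:
            assert classify(v, loaded) == classify(v, small_bank)
        np.testing.assert_array_equal(
            loaded.models["<complete>"].train, small_bank.models["<complete>"].train
        )
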