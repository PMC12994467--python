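"""Segment-wise tree-ensemble regression with participant-level splitting."""

import numpy as np
import pandas as pd
import pytest

from pronecg import (
    SegmentKind,
    build_feature_table,
    cohort_feature_tables,
    convert_approach3,
    crossvalidate,
    feature_importance,
    participant_split,
    predict_full_beat,
    train_segment_models,
)
from pronecg.approach3 import (
    FEATURE_NAMES,
    RF_DEFAULTS,
    SEGMENT_LENGTHS,
    XGB_DEFAULTS,
    assert_no_leakage,
)
from pronecg.delineation import segment_windows
from pronecg.errors import (
    EmptySlot,
    LeakageError,
    MissingCovariate,
    ModelNotFitted,
    TooManyFolds,
)


@pytest.fixture(scope="module")
def qrs_tables(clean_cohort):
    return cohort_feature_tables(clean_cohort, segments=(SegmentKind.QRS,))


@pytest.fixture(scope="module")
def small_bundle(clean_cohort):
    tables = cohort_feature_tables(clean_cohort)
    return train_segment_models(tables, "random_forest", {"ntree": 30}, seed=5), tables


class TestFeatureTable:
    def test_eighteen_features_per_row(self, clean_cohort):
        s = clean_cohort.subjects[0]
        df = build_feature_table(s.prone, s.fiducials[0], s.supine, s.fiducials[0],
                                 s.covariates, SegmentKind.QRS)
        assert len(FEATURE_NAMES) == 18
        assert all(c in df.columns for c in FEATURE_NAMES)

    @pytest.mark.parametrize("segment,length", [
        (SegmentKind.PR, 50), (SegmentKind.QRS, 60), (SegmentKind.STT, 200)])
    def test_normalised_lengths(self, clean_cohort, segment, length):
        s = clean_cohort.subjects[0]
        df = build_feature_table(s.prone, s.fiducials[0], s.supine, s.fiducials[0],
                                 s.covariates, segment)
        assert len(df) == length == SEGMENT_LENGTHS[segment]

    def test_missing_covariates_raise(self, clean_cohort):
        s = clean_cohort.subjects[0]
        with pytest.raises(MissingCovariate):
            build_feature_table(s.prone, s.fiducials[0], s.supine, s.fiducials[0],
                                None, SegmentKind.QRS)

    def test_no_missing_values_and_groups(self, qrs_tables):
        df = qrs_tables[SegmentKind.QRS]
        assert not df.isna().any().any()
        assert df["group"].nunique() == 10


class TestParticipantSplit:
    def test_study_split_sizes(self):
        ids = [f"S{i:03d}" for i in range(70)]
        train, test = participant_split(ids, 0.8, seed=0)
        assert (len(train), len(test)) == (56, 14)

    @pytest.mark.parametrize("seed", [0, 1, 99])
    def test_disjoint_and_exhaustive(self, seed):
        ids = [f"S{i}" for i in range(23)]
        train, test = participant_split(ids, 0.8, seed=seed)
        assert not set(train) & set(test)
        assert sorted(train + test) == sorted(ids)

    def test_deterministic_given_seed(self):
        ids = [f"S{i}" for i in range(30)]
        assert participant_split(ids, 0.8, 7) == participant_split(ids, 0.8, 7)

    def test_leakage_guard_raises(self):
        with pytest.raises(LeakageError):
            assert_no_leakage(["a", "b"], ["b", "c"])


class TestTraining:
    def test_default_hyperparameters_reported(self, qrs_tables):
        rf = train_segment_models(qrs_tables, "random_forest", None, seed=0,
                                  leads=("V1",), segments=(SegmentKind.QRS,))
        assert rf.params == RF_DEFAULTS
        xgb = train_segment_models(qrs_tables, "gradient_boosted_trees", None,
                                   seed=0, leads=("V1",), segments=(SegmentKind.QRS,))
        assert xgb.params == XGB_DEFAULTS
        assert xgb.params["eta"] == 0.1 and xgb.params["max_depth"] == 2

    def test_deterministic_predictions(self, qrs_tables):
        X = qrs_tables[SegmentKind.QRS][list(FEATURE_NAMES)].to_numpy()[:50]
        preds = []
        for _ in range(2):
            b = train_segment_models(qrs_tables, "random_forest", {"ntree": 20},
                                     seed=3, leads=("V2",), segments=(SegmentKind.QRS,))
            preds.append(b.predict("V2", SegmentKind.QRS, X))
        assert np.array_equal(preds[0], preds[1])

    def test_empty_slot_raises(self, qrs_tables):
        empty = {SegmentKind.QRS: qrs_tables[SegmentKind.QRS].iloc[0:0]}
        with pytest.raises(EmptySlot):
            train_segment_models(empty, "random_forest", {"ntree": 5},
                                 segments=(SegmentKind.QRS,))

    def test_training_restricted_to_train_subjects(self, clean_cohort, qrs_tables):
        ids = clean_cohort.subject_ids()
        train, test = participant_split(ids, 0.8, seed=1)
        # restricting to a missing id set empties the slot
        with pytest.raises(EmptySlot):
            train_segment_models(qrs_tables, "random_forest", {"ntree": 5},
                                 train_subjects=["nope"], segments=(SegmentKind.QRS,))
        b = train_segment_models(qrs_tables, "random_forest", {"ntree": 10},
                                 train_subjects=train, leads=("V1",),
                                 segments=(SegmentKind.QRS,))
        assert ("V1", SegmentKind.QRS) in b.models


class TestCrossValidation:
    def test_summary_matches_per_fold_recomputation(self, qrs_tables):
        df = crossvalidate(qrs_tables, "random_forest", {"ntree": 10}, k=3,
                           leads=("V1",), segments=(SegmentKind.QRS,))
        folds = df[df.fold.isin(["0", "1", "2"])]
        mean_row = df[df.fold == "mean"].iloc[0]
        assert mean_row.r2 == pytest.approx(folds.r2.mean())
        assert mean_row.rmse == pytest.approx(folds.rmse.mean())
        sd_row = df[df.fold == "sd"].iloc[0]
        assert sd_row.r2 == pytest.approx(folds.r2.std(ddof=1))

    def test_too_many_folds(self, qrs_tables):
        with pytest.raises(TooManyFolds):
            crossvalidate(qrs_tables, "random_forest", {"ntree": 5}, k=11,
                          leads=("V1",), segments=(SegmentKind.QRS,))


class TestPrediction:
    def test_beat_covers_windows_without_steps(self, clean_cohort, small_bundle):
        bundle, _ = small_bundle
        s = clean_cohort.subjects[0]
        fid = s.fiducials[1]
        beat = predict_full_beat(bundle, s.prone, fid, s.covariates)
        pr, qrs, stt = segment_windows(fid, s.prone.fs)
        for lead in ("V1", "V3"):
            y = beat[lead]
            assert np.all(y[: pr.start] == 0.0)
            assert np.all(y[stt.end:] == 0.0)
            # no step larger than 0.05 mV at any window boundary
            for b in (pr.start, qrs.start, stt.start):
                assert abs(y[b] - y[b - 1]) < 0.05

    def test_stt_model_isolated_from_qrs_window(self, clean_cohort, small_bundle):
        bundle, tables = small_bundle
        s = clean_cohort.subjects[0]
        fid = s.fiducials[1]
        before = predict_full_beat(bundle, s.prone, fid, s.covariates)

        class _Zero:
            def predict(self, X):
                return np.zeros(len(X))

        import copy

        altered = copy.copy(bundle)
        altered.models = dict(bundle.models)
        altered.models[("V1", SegmentKind.STT)] = _Zero()
        after = predict_full_beat(altered, s.prone, fid, s.covariates)
        _, qrs, _ = segment_windows(fid, s.prone.fs)
        assert np.array_equal(before["V1"][qrs.start:qrs.end],
                              after["V1"][qrs.start:qrs.end])

    def test_unfitted_bundle_raises(self, clean_cohort, qrs_tables):
        partial = train_segment_models(qrs_tables, "random_forest", {"ntree": 5},
                                       leads=("V1",), segments=(SegmentKind.QRS,))
        s = clean_cohort.subjects[0]
        with pytest.raises(ModelNotFitted):
            predict_full_beat(partial, s.prone, s.fiducials[0], s.covariates)

    def test_record_conversion_passes_through_v6_and_limbs(self, clean_cohort,
                                                           small_bundle):
        bundle, _ = small_bundle
        s = clean_cohort.subjects[0]
        out = convert_approach3(bundle, s.prone, s.fiducials, s.covariates)
        for lead in ("I", "II", "aVF", "V6"):
            assert np.array_equal(out.lead(lead), s.prone.lead(lead))


class TestFeatureImportance:
    def test_inverse_partner_ranks_first_for_v1(self, small_bundle):
        bundle, _ = small_bundle
        imp = feature_importance(bundle)
        top = imp[(imp.lead == "V1") & (imp.segment == "QRS") & (imp["rank"] == 0)]
        assert top.feature.iloc[0] == "prone_V4"

    def test_importances_nonnegative_and_deterministic(self, small_bundle):
        bundle, _ = small_bundle
        a = feature_importance(bundle)
        b = feature_importance(bundle)
        assert (a.importance >= 0).all()
        pd.testing.assert_frame_equal(a, b)


class TestGeneralisation:
    def test_heldout_r2_high_on_noise_free_cohort(self):
        # larger cohort so held-out subjects fall inside the training range
        from pronecg import SyntheticCohortConfig, simulate_cohort

        cfg = SyntheticCohortConfig(n_subjects=30, total_beats=250,
                                    noise_sd=0.0, seed=17)
        co = simulate_cohort(cfg)
        tables = cohort_feature_tables(co, segments=(SegmentKind.QRS,))
        train, test = participant_split(co.subject_ids(), 0.8, seed=17)
        df = tables[SegmentKind.QRS]
        te = df[df.group.isin(test)]
        X = te[list(FEATURE_NAMES)].to_numpy()
        for algo, floor in (("random_forest", 0.9), ("gradient_boosted_trees", 0.9)):
            bundle = train_segment_models(
                tables, algo, {"ntree": 100, "nrounds": 300}, seed=17,
                train_subjects=train, leads=("V3",), segments=(SegmentKind.QRS,))
            pred = bundle.predict("V3", SegmentKind.QRS, X)
            y = te["target_V3"].to_numpy()
            ss = 1 - np.sum((y - pred) ** 2) / np.sum((y - y.mean()) ** 2)
            assert ss >= floor
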