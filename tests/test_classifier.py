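"""Feature assembly, group-wise splitting, the forest, cross-tables,
cross-validation and leave-one-out attribution."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from neuroihc.classifier import (
    ClassifierConfig,
    FeatureMatrix,
    assemble_features,
    cross_validate,
    crosstable_from_predictions,
    evaluate,
    leave_one_out,
    make_crosstable,
    split_train_test,
    train_forest,
)
from neuroihc.cohort import generate_cohort_table
from neuroihc.effects import null_effects, study_effects
from neuroihc.featuresim import informative_noise_detections, sample_detections
from neuroihc.sampling import enumerate_plan


@pytest.fixture(scope="module")
def detection_fm(small_cohort_m, small_plan_m):
    det = sample_detections(
        small_plan_m,
        small_cohort_m,
        study_effects(seed=2),
        seed=21,
        n_superpixels_per_roi=10,
        n_cells_per_roi=3,
    )
    return assemble_features(det, small_plan_m, small_cohort_m)


@pytest.fixture(scope="module")
def small_cohort_m():
    return generate_cohort_table(4, 4, seed=11)


@pytest.fixture(scope="module")
def small_plan_m(small_cohort_m):
    return enumerate_plan(small_cohort_m, stains=("Iba1", "FUS"), regions=("BA4",), n_replicates=2)


def _noise_fm(n_rois=30, n_noise=3, shift=0.0, seed=0, rows=6):
    det = informative_noise_detections(n_rois, n_noise, shift, seed, rows_per_roi=rows)
    plan = det[["roi_id", "case_id", "stain", "region", "matter", "adjacency"]].drop_duplicates()
    plan = plan.assign(replicate=1)
    cohort = pd.DataFrame(
        {
            "case_id": det["case_id"].unique(),
            "group": ["disease" if c.startswith("ALS") else "control" for c in det["case_id"].unique()],
        }
    )
    return assemble_features(det.drop(columns=["label"]), plan, cohort)


class TestAssembleFeatures:
    def test_empty_records_give_empty_matrix(self, small_plan_m, small_cohort_m):
        fm = assemble_features(pd.DataFrame(columns=["roi_id"]), small_plan_m, small_cohort_m)
        assert len(fm) == 0

    def test_orphan_roi_ids_rejected(self, small_plan_m, small_cohort_m):
        det = pd.DataFrame({"roi_id": ["nonexistent"], "mean_dab_od": [0.3]})
        with pytest.raises(ValueError, match="nonexistent"):
            assemble_features(det, small_plan_m, small_cohort_m)

    def test_every_feature_column_is_group_tagged(self, detection_fm):
        meta = {"roi_id", "case_id", "stain", "region", "matter", "adjacency", "label"}
        for c in detection_fm.data.columns:
            assert c in meta or c in detection_fm.feature_groups

    def test_sentinels_paired_with_indicators(self, detection_fm):
        df = detection_fm.data
        assert not df[detection_fm.features].isna().any().any()
        assert "dist_to_vessel_um_missing" in df.columns

    def test_row_bookkeeping(self, detection_fm, small_plan_m):
        # 10 superpixels per ROI plus 3 cells per FUS ROI
        n_fus = (small_plan_m["stain"] == "FUS").sum()
        assert len(detection_fm) == 10 * len(small_plan_m) + 3 * n_fus


class TestSplit:
    def test_group_exclusivity(self, detection_fm):
        train, test = split_train_test(detection_fm, 0.66, unit="roi", seed=3)
        assert not set(train.data["roi_id"]) & set(test.data["roi_id"])

    def test_same_seed_identical(self, detection_fm):
        a = split_train_test(detection_fm, 0.66, unit="roi", seed=4)[0]
        b = split_train_test(detection_fm, 0.66, unit="roi", seed=4)[0]
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_split_fraction_arithmetic(self, detection_fm):
        train, test = split_train_test(detection_fm, 0.66, unit="roi", seed=5)
        n_train = train.data["roi_id"].nunique()
        n_total = detection_fm.data["roi_id"].nunique()
        assert n_train == pytest.approx(0.66 * n_total, abs=2)

    def test_label_proportions_preserved(self, detection_fm):
        train, test = split_train_test(detection_fm, 0.66, unit="roi", seed=6)
        p_all = (detection_fm.data["label"] == "disease").mean()
        assert (train.data["label"] == "disease").mean() == pytest.approx(p_all, abs=0.05)
        assert (test.data["label"] == "disease").mean() == pytest.approx(p_all, abs=0.05)

    def test_case_unit_keeps_cases_together(self, detection_fm):
        train, test = split_train_test(detection_fm, 0.66, unit="case", seed=7)
        assert not set(train.data["case_id"]) & set(test.data["case_id"])

    def test_single_label_rejected(self, detection_fm):
        only_disease = detection_fm.subset(detection_fm.data["label"] == "disease")
        with pytest.raises(ValueError):
            split_train_test(only_disease, 0.66, unit="roi", seed=1)


class TestCrossTable:
    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(tp=st.integers(0, 40), fn=st.integers(0, 40), tn=st.integers(0, 40), fp=st.integers(0, 40))
    def test_formulas_match_hand_computation(self, tp, fn, tn, fp):
        ct = make_crosstable(tp, fn, tn, fp)
        if tp + fn:
            assert ct.sensitivity == pytest.approx(100.0 * tp / (tp + fn))
        if tn + fp:
            assert ct.specificity == pytest.approx(100.0 * tn / (tn + fp))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(tp=st.integers(1, 60), fn=st.integers(1, 60), tn=st.integers(1, 60), fp=st.integers(1, 60))
    def test_chi2_matches_independent_pearson_oracle(self, tp, fn, tn, fp):
        """Hand-computed Pearson statistic + chi2 tail agree to 1e-10."""
        ct = make_crosstable(tp, fn, tn, fp)
        obs = np.array([[tp, fn], [fp, tn]], dtype=float)
        n = obs.sum()
        exp = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n
        if (exp == 0).any():
            return
        chi2 = float(((obs - exp) ** 2 / exp).sum())
        assert ct.chi2_stat == pytest.approx(chi2, abs=1e-10)
        assert ct.chi2_p == pytest.approx(stats.chi2.sf(chi2, df=1), abs=1e-10)

    def test_published_formula_example(self):
        ct = make_crosstable(tp=69, fn=31, tn=66, fp=34)
        assert ct.sensitivity == pytest.approx(69.0)
        assert ct.specificity == pytest.approx(66.0)

    def test_balanced_table_has_no_association(self):
        ct = make_crosstable(25, 25, 25, 25)
        assert ct.sensitivity == 50 and ct.specificity == 50
        assert ct.chi2_p == pytest.approx(1.0)

    def test_perfect_classification(self):
        ct = make_crosstable(100, 0, 100, 0)
        assert ct.sensitivity == 100 and ct.specificity == 100

    def test_empty_margin_flagged_untested(self):
        ct = make_crosstable(10, 5, 0, 0)
        assert not ct.tested and np.isnan(ct.chi2_p)

    def test_negative_cells_rejected(self):
        with pytest.raises(ValueError):
            make_crosstable(-1, 0, 0, 0)


class TestForest:
    def test_pure_signal_reaches_perfect_training_accuracy(self):
        fm = _noise_fm(n_rois=20, n_noise=0, shift=50.0, seed=1)
        cc = ClassifierConfig(n_trees=20, seed=2)
        train, _ = split_train_test(fm, 0.66, unit="roi", seed=2)
        model = train_forest(train, cc)
        acc = (model.predict(train) == train.data["label"]).mean()
        assert acc == 1.0

    def test_single_class_rejected(self):
        fm = _noise_fm(n_rois=10, seed=3)
        disease_only = fm.subset(fm.data["label"] == "disease")
        with pytest.raises(ValueError):
            train_forest(disease_only, ClassifierConfig(n_trees=5))

    def test_null_features_classify_at_chance(self):
        """Label-independent features: sensitivity+specificity near 100."""
        scores = []
        for seed in range(5):
            fm = _noise_fm(n_rois=60, n_noise=4, shift=0.0, seed=seed, rows=8)
            cc = ClassifierConfig(n_trees=25, seed=seed)
            train, test = split_train_test(fm, 0.66, unit="roi", seed=seed)
            model = train_forest(train, cc)
            ct = crosstable_from_predictions(test.data["label"].to_numpy(), model.predict(test))
            scores.append(ct.sensitivity + ct.specificity)
        assert np.mean(scores) == pytest.approx(100.0, abs=12.0)

    def test_planted_feature_group_shift_is_learnable(self):
        """2-sigma detection-level shift: sens and spec both above 80%."""
        fm = _noise_fm(n_rois=500, n_noise=4, shift=2.0, seed=9, rows=20)
        cc = ClassifierConfig(n_trees=60, seed=9)
        train, test = split_train_test(fm, 0.66, unit="roi", seed=9)
        model = train_forest(train, cc)
        ct = crosstable_from_predictions(test.data["label"].to_numpy(), model.predict(test))
        assert ct.sensitivity > 80 and ct.specificity > 80

    def test_seeded_determinism(self, detection_fm):
        cc = ClassifierConfig(n_trees=10, seed=5)
        train, test = split_train_test(detection_fm, 0.66, unit="roi", seed=5)
        a = train_forest(train, cc).predict(test)
        b = train_forest(train, cc).predict(test)
        assert np.array_equal(a, b)


class TestEvaluate:
    def test_hierarchy_depths_and_strata(self, detection_fm):
        cc = ClassifierConfig(n_trees=10, seed=6)
        train, test = split_train_test(detection_fm, 0.66, unit="roi", seed=6)
        report = evaluate(train_forest(train, cc), test)
        assert sorted(report.strata["depth"].unique()) == [1, 2, 3, 4]
        d1 = report.strata[report.strata["depth"] == 1]
        assert set(d1["stain"]) <= {"Iba1", "FUS"}

    def test_stratum_counts_sum_to_test_rows(self, detection_fm):
        cc = ClassifierConfig(n_trees=10, seed=6)
        train, test = split_train_test(detection_fm, 0.66, unit="roi", seed=6)
        report = evaluate(train_forest(train, cc), test)
        for depth in (1, 2, 3, 4):
            assert report.strata.loc[report.strata["depth"] == depth, "n"].sum() == len(test)


class TestCrossValidate:
    def test_folds_partition_rois(self, detection_fm):
        cc = ClassifierConfig(n_trees=8, cv_folds=3, seed=7)
        per_fold, summary = cross_validate(detection_fm, cc)
        assert len(per_fold) == 3
        assert per_fold["n_test"].sum() == len(detection_fm)
        assert np.isfinite(summary["sensitivity_mean"])

    def test_too_many_folds_rejected(self):
        fm = _noise_fm(n_rois=4, seed=1)
        with pytest.raises(ValueError):
            cross_validate(fm, ClassifierConfig(n_trees=5, cv_folds=10))


class TestLeaveOneOut:
    def test_duplicated_feature_is_redundant(self):
        fm = _noise_fm(n_rois=60, n_noise=2, shift=2.0, seed=4, rows=10)
        dup = fm.data.copy()
        dup["signal_copy"] = dup["signal"]
        fm2 = FeatureMatrix(dup, {**fm.feature_groups, "signal_copy": "staining-intensity"})
        cc = ClassifierConfig(n_trees=40, seed=4)
        loo, _ = leave_one_out(fm2, cc, unit="feature")
        drop_one_copy = loo.set_index("unit").loc["signal_copy"]
        assert abs(drop_one_copy["delta_sensitivity"]) < 8
        assert abs(drop_one_copy["delta_specificity"]) < 8

    def test_feature_group_unit(self, detection_fm):
        cc = ClassifierConfig(n_trees=8, seed=8)
        loo, ranking = leave_one_out(detection_fm, cc, unit="feature_group")
        assert set(loo["unit"]) <= {
            "staining-intensity",
            "staining-extent",
            "morphology-area",
            "morphology-shape",
            "spatial-vessel",
            "spatial-position",
        }
        assert len(ranking) == len(detection_fm.features)

    def test_single_feature_matrix_rejected(self):
        fm = _noise_fm(n_rois=10, n_noise=0, shift=1.0, seed=2)
        with pytest.raises(ValueError):
            leave_one_out(fm, ClassifierConfig(n_trees=5), unit="feature")
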