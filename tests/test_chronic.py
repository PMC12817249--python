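"""Chronic-stress stage: labels from scales, feature assembly,
subject-level splitting, classifier training and the SSCI3 regression."""

import numpy as np
import pandas as pd
import pytest

from stressci import baseline, chronic, cohort
from stressci.errors import (ConfigError, InvalidParameterError,
                             MissingDataError)


def _constant_models(cort=150.0, glu=80.0):
    return {"cortisol": baseline.constant_baseline("cortisol", cort),
            "glucose": baseline.constant_baseline("glucose", glu)}


@pytest.fixture(scope="module")
def small_cohort():
    table = cohort.generate_depression_cohort(seed=5)
    return pd.concat([table, chronic.make_labels(table)], axis=1)


class TestLabels:
    def test_scale_minima_map_to_nd(self):
        label = chronic.label_from_scales(90.0, 25.0, 25.0)
        assert label.composite_score == pytest.approx(0.0)
        assert label.class4 == "ND" and label.class2 == "healthy"

    def test_scale_maxima_map_to_sd(self):
        label = chronic.label_from_scales(450.0, 100.0, 100.0)
        assert label.composite_score == pytest.approx(1.0)
        assert label.class4 == "SD" and label.class2 == "patient"

    def test_boundary_goes_to_higher_class(self):
        # all label weight on SCL-90 so the composite is exactly 0.25,
        # landing on the first threshold: the higher class (DR) wins
        weights = {"SCL90": 1.0, "SDS": 0.0, "SAS": 0.0}
        label = chronic.label_from_scales(180.0, 25.0, 25.0, weights=weights,
                                          thresholds=(0.25, 0.5, 0.75))
        assert label.composite_score == 0.25
        assert label.class4 == "DR"

    def test_out_of_range_score_rejected(self):
        with pytest.raises(InvalidParameterError):
            chronic.label_from_scales(500.0, 25.0, 25.0)

    def test_bad_weights_rejected(self):
        with pytest.raises(ConfigError):
            chronic.label_from_scales(90.0, 25.0, 25.0, weights={"SCL90": 1.0})

    def test_class2_collapse(self):
        assert chronic.class2_of("ND") == "healthy"
        assert chronic.class2_of("DR") == "healthy"
        assert chronic.class2_of("MD") == "patient"
        assert chronic.class2_of("SD") == "patient"


class TestFeatures:
    def test_vector_has_nine_columns(self, small_cohort):
        X = chronic.assemble_features(small_cohort, _constant_models())
        assert list(X.columns) == list(chronic.FEATURE_NAMES)
        assert X.shape == (len(small_cohort), 9)

    def test_non_temporal_passes_raw_values(self, small_cohort):
        X = chronic.assemble_features(small_cohort, {}, temporal=False)
        np.testing.assert_array_equal(X["cortisol_adj"], small_cohort["cortisol"])

    def test_benchmark_time_row_unchanged(self, small_cohort):
        row = small_cohort.iloc[[0]].copy()
        row["time"] = 8.0
        models = baseline.fit_reference_baselines(seed=2)
        a = chronic.assemble_features(row, models, temporal=True)
        b = chronic.assemble_features(row, models, temporal=False)
        pd.testing.assert_frame_equal(a, b)

    def test_missing_demographic_rejected(self, small_cohort):
        broken = small_cohort.drop(columns=["mean_bp"])
        with pytest.raises(MissingDataError):
            chronic.assemble_features(broken, _constant_models())


class TestSplit:
    def test_default_split_is_117_30(self, small_cohort):
        train, test = chronic.split_cohort(small_cohort, 10, seed=0)
        assert len(train) == 117 and len(test) == 30

    def test_no_subject_straddles_partitions(self, small_cohort):
        for seed in range(5):
            train, test = chronic.split_cohort(small_cohort, 10, seed=seed)
            assert not set(train["subject_id"]) & set(test["subject_id"])

    def test_seed_reproducible(self, small_cohort):
        a = chronic.split_cohort(small_cohort, 10, seed=3)
        b = chronic.split_cohort(small_cohort, 10, seed=3)
        pd.testing.assert_frame_equal(a[0], b[0])

    def test_too_many_test_subjects_rejected(self, small_cohort):
        with pytest.raises(InvalidParameterError):
            chronic.split_cohort(small_cohort, 49, seed=0)


class TestNormalization:
    def test_fit_on_train_only(self):
        train = pd.DataFrame({"a": [0.0, 10.0], "b": [5.0, 15.0]})
        test = pd.DataFrame({"a": [20.0], "b": [-5.0]})
        norm = chronic.MinMaxNorm.fit(train)
        out = norm.transform(test)
        # test values may fall outside [0, 1]: no peeking at test statistics
        assert out["a"].iloc[0] == pytest.approx(2.0)
        assert out["b"].iloc[0] == pytest.approx(-1.0)

    def test_constant_column_passes_through(self):
        train = pd.DataFrame({"a": [3.0, 3.0, 3.0]})
        norm = chronic.MinMaxNorm.fit(train)
        assert not norm.transform(train)["a"].isna().any()


@pytest.fixture(scope="module")
def fitted(small_cohort):
    models = baseline.fit_reference_baselines(seed=2)
    train, test = chronic.split_cohort(small_cohort, 10, seed=1)
    X_train = chronic.assemble_features(train, models)
    X_test = chronic.assemble_features(test, models)
    bundle = chronic.train_classifiers(X_train, train["class4"], seed=1)
    return bundle, X_test, test


class TestClassifiers:
    def test_confusion_row_sums_match_class_counts(self, fitted):
        bundle, X_test, test = fitted
        metrics = chronic.evaluate(bundle, X_test, test["class4"])
        for m in metrics.values():
            counts = test["class4"].value_counts()
            expected = [counts.get(c, 0) for c in m["confusion_labels"]]
            np.testing.assert_array_equal(m["confusion"].sum(axis=1), expected)

    def test_same_seed_identical_predictions(self, fitted, small_cohort):
        bundle, X_test, _ = fitted
        models = baseline.fit_reference_baselines(seed=2)
        train, _ = chronic.split_cohort(small_cohort, 10, seed=1)
        X_train = chronic.assemble_features(train, models)
        bundle2 = chronic.train_classifiers(X_train, train["class4"], seed=1)
        for name in bundle.models:
            np.testing.assert_array_equal(bundle.predict(name, X_test),
                                          bundle2.predict(name, X_test))

    def test_single_class_training_rejected(self, small_cohort):
        nd_only = small_cohort[small_cohort["class4"] == "ND"]
        X = chronic.assemble_features(nd_only, _constant_models())
        with pytest.raises(InvalidParameterError):
            chronic.train_classifiers(X, nd_only["class4"], seed=0)

    def test_perfect_classifier_has_unit_aucs(self):
        """A degenerately separable binary problem yields ROC/PR AUC = 1."""
        X = pd.DataFrame({"x": np.r_[np.zeros(20), np.ones(20)],
                          "y": np.r_[np.zeros(20), np.ones(20)]})
        y4 = np.array(["ND"] * 20 + ["SD"] * 20)
        bundle = chronic.train_classifiers(
            X, y4, algorithms={"RF": chronic.default_algorithms(0)["RF"]})
        metrics = chronic.evaluate(bundle, X, y4)
        assert metrics["RF"]["roc_auc"] == pytest.approx(1.0)
        assert metrics["RF"]["pr_auc"] == pytest.approx(1.0)


class TestSsci3Regression:
    def test_exact_linear_labels_recovered(self, small_cohort):
        models = _constant_models()
        X = chronic.assemble_features(small_cohort, models)
        beta = np.arange(1.0, 10.0)
        y = chronic.MinMaxNorm.fit(X).transform(X).to_numpy() @ beta + 0.5
        n = len(X)
        out = chronic.regress_ssci3(X.iloc[:n // 2], y[:n // 2],
                                    X.iloc[n // 2:], y[n // 2:])
        assert out["test_corr"] == pytest.approx(1.0, abs=1e-8)

    def test_intercept_only_features_give_zero_correlation(self):
        X = pd.DataFrame({"a": np.ones(40), "b": np.full(40, 2.0)})
        y = np.random.default_rng(0).normal(size=40)
        out = chronic.regress_ssci3(X.iloc[:30], y[:30], X.iloc[30:], y[30:])
        assert out["test_corr"] == pytest.approx(0.0, abs=1e-12)


class TestStability:
    def _day_table(self, cort, glu, n=8):
        t = np.linspace(8.0, 22.0, n)
        return pd.DataFrame({
            "subject_id": "P1", "time": t, "cortisol": cort, "glucose": glu,
            "st": 34.5, "hr": 72.0, "gender": "F", "age": 40.0,
            "height": 165.0, "weight": 60.0, "mean_bp": 90.0})

    def _regressor(self, small_cohort, models):
        X = chronic.assemble_features(small_cohort, models)
        return chronic.regress_ssci3(
            X, small_cohort["composite_score"])["regressor"]

    def test_constant_subject_with_constant_baselines_has_zero_rsd(self, small_cohort):
        models = _constant_models()
        day = self._day_table(150.0, 80.0)
        reg = self._regressor(small_cohort, models)
        out = chronic.stability_comparison(day, models, reg)
        assert out["rsd_adjusted"] == pytest.approx(0.0, abs=1e-9)
        assert out["rsd_raw"] == pytest.approx(0.0, abs=1e-9)

    def test_rhythmic_subject_stabilized_by_adjustment(self, small_cohort):
        models = baseline.fit_reference_baselines(seed=2)
        rng = np.random.default_rng(3)
        prof = cohort.draw_profile(rng, "P1")
        t = np.linspace(8.0, 22.0, 8)
        day = self._day_table(
            cohort.simulate_cortisol_diurnal(prof, t, 2.0, 3),
            cohort.simulate_glucose(prof, t, noise_sd=2.0, seed=4))
        reg = self._regressor(small_cohort, models)
        out = chronic.stability_comparison(day, models, reg)
        assert out["rsd_adjusted"] < out["rsd_raw"]

    def test_too_few_points_rejected(self, small_cohort):
        models = _constant_models()
        day = self._day_table(150.0, 80.0, n=3)
        reg = self._regressor(small_cohort, models)
        with pytest.raises(InvalidParameterError):
            chronic.stability_comparison(day, models, reg)
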