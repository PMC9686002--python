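"""LOSO classification: folds, pipeline hygiene, pooled reporting."""

import numpy as np
import pandas as pd
import pytest

import painhrv as ph
from painhrv.classify import FoldResult, report_from_folds
from painhrv.errors import ConfigError, InvalidDatasetError
from painhrv.features import FEATURE_FAMILIES, FEATURE_NAMES


class TestF1:
    @pytest.mark.parametrize(
        "precision,recall,expected",
        [
            (0.765, 0.861, 0.811),
            (0.875, 0.785, 0.828),
            (0.736, 0.844, 0.786),
            (0.856, 0.754, 0.801),
            (1.0, 1.0, 1.0),
        ],
    )
    def test_harmonic_mean_reproduces_reported_cells(self, precision, recall, expected):
        # inputs are 3-decimal roundings, so match to one unit in the last digit
        assert ph.f1_from_precision_recall(precision, recall) == pytest.approx(
            expected, abs=1e-3
        )

    def test_zero_denominator_defined_as_zero(self):
        assert ph.f1_from_precision_recall(0.0, 0.0) == 0.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ph.f1_from_precision_recall(1.2, 0.5)


class TestFolds:
    def test_three_subject_enumeration(self):
        folds = ph.loso_folds(np.array(["A", "B", "C", "A", "B"]))
        assert folds == [(["B", "C"], "A"), (["A", "C"], "B"), (["A", "B"], "C")]

    def test_folds_cover_each_subject_once_disjointly(self):
        ids = np.repeat([f"S{i}" for i in range(7)], 3)
        folds = ph.loso_folds(ids)
        assert sorted(test for _, test in folds) == sorted(set(ids))
        for train, test in folds:
            assert test not in train

    def test_single_subject_rejected(self):
        with pytest.raises(InvalidDatasetError):
            ph.loso_folds(np.array(["A", "A"]))


class TestSelectFeatures:
    def test_field_set_is_the_18_time_domain_columns(self, small_dataset):
        X, _, _ = small_dataset
        field = ph.select_features(X, "field")
        assert field.shape[1] == 18
        assert all(FEATURE_FAMILIES[c] == "time_domain" for c in field.columns)

    def test_laboratory_set_keeps_all_46(self, small_dataset):
        X, _, _ = small_dataset
        assert ph.select_features(X, "laboratory").shape[1] == 46
        assert list(ph.select_features(X, "laboratory").columns) == FEATURE_NAMES

    def test_unknown_set_rejected(self, small_dataset):
        X, _, _ = small_dataset
        with pytest.raises(ConfigError):
            ph.select_features(X, "mobile")


def separable_data(n_per_class=30, n_features=6, seed=0):
    rng = np.random.default_rng(seed)
    X0 = rng.normal(0.0, 1.0, size=(n_per_class, n_features))
    X1 = rng.normal(0.0, 1.0, size=(n_per_class, n_features))
    X1[:, 0] += 20.0  # one hugely informative dimension
    X = pd.DataFrame(np.vstack([X0, X1]),
                     columns=[f"f{i}" for i in range(n_features)])
    y = np.array(["BL"] * n_per_class + ["CPT"] * n_per_class)
    return X, y


class TestFitFold:
    def test_scaler_standardizes_training_columns(self):
        X, y = separable_data()
        fitted = ph.fit_fold(X, y, ph.ModelConfig(feature_set="laboratory"))
        scaler = fitted.pipeline.named_steps["scale"]
        Z = scaler.transform(X.to_numpy())
        assert np.allclose(Z.mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(Z.std(axis=0), 1.0, atol=1e-9)

    def test_full_variance_retention_keeps_all_components(self):
        X, y = separable_data(n_per_class=40, n_features=5)
        fitted = ph.fit_fold(
            X, y, ph.ModelConfig(pca_variance_retained=1.0)
        )
        assert fitted.n_components_retained == min(len(X) - 1, 5)

    def test_separable_classes_fit_perfectly(self):
        X, y = separable_data()
        fitted = ph.fit_fold(X, y, ph.ModelConfig())
        assert (fitted.predict(X) == y).mean() == 1.0

    def test_single_class_training_rejected(self):
        X, y = separable_data()
        with pytest.raises(InvalidDatasetError):
            ph.fit_fold(X, np.array(["BL"] * len(y)), ph.ModelConfig())


class TestEvaluateLoso:
    def test_supports_pool_to_total_observations(self, small_dataset):
        X, y, groups = small_dataset
        report = ph.evaluate_loso(X, y, groups, ph.ModelConfig(feature_set="field"))
        assert report.support["BL"] + report.support["CPT"] == len(y)
        assert report.n_folds == len(np.unique(groups))
        for cls in ("BL", "CPT"):
            assert 0.0 <= report.f1[cls] <= 1.0

    def test_metric_identity_and_recall_support_consistency(self, small_dataset):
        X, y, groups = small_dataset
        report = ph.evaluate_loso(X, y, groups, ph.ModelConfig(feature_set="field"))
        for cls in ("BL", "CPT"):
            assert report.f1[cls] == pytest.approx(
                ph.f1_from_precision_recall(report.precision[cls], report.recall[cls])
            )
            tp = report.recall[cls] * report.support[cls]
            assert tp == pytest.approx(round(tp), abs=1e-9)

    def test_determinism(self, small_dataset):
        X, y, groups = small_dataset
        cfg = ph.ModelConfig(feature_set="laboratory", seed=7)
        assert ph.evaluate_loso(X, y, groups, cfg) == ph.evaluate_loso(X, y, groups, cfg)

    def test_no_leakage_refit_without_test_rows_is_identical(self, small_dataset):
        """Re-fitting any fold after deleting the held-out subject's rows
        from the training input leaves its predictions unchanged — i.e. the
        fold never saw those rows."""
        X, y, groups = small_dataset
        cfg = ph.ModelConfig(feature_set="field", seed=0)
        folds = ph.run_loso(X, y, groups, cfg)
        Xf = ph.select_features(X, "field")
        for fold in folds[:3]:
            train_mask = groups != fold.test_subject
            refit = ph.fit_fold(Xf.loc[train_mask], y[train_mask], cfg)
            assert np.array_equal(refit.predict(fold.test_features), fold.predictions)

    def test_report_rendering_contains_both_classes(self, small_dataset):
        X, y, groups = small_dataset
        report = ph.evaluate_loso(X, y, groups, ph.ModelConfig(feature_set="field"))
        text = report.to_text()
        assert "BL" in text and "CPT" in text and "18 features" in text


class TestReportFromFolds:
    def test_pooling_over_hand_built_folds(self):
        """Pooled metrics equal a direct confusion-matrix computation on
        the concatenated predictions (independent arithmetic)."""
        y1, p1 = np.array(["BL", "BL", "CPT"]), np.array(["BL", "CPT", "CPT"])
        y2, p2 = np.array(["CPT", "BL"]), np.array(["CPT", "BL"])
        folds = [
            FoldResult("A", None, pd.DataFrame(), y1, p1),
            FoldResult("B", None, pd.DataFrame(), y2, p2),
        ]
        report = report_from_folds(folds, ph.ModelConfig())
        # pooled truth: BL x3 (2 right), CPT x2 (2 right)
        assert report.support == {"BL": 3, "CPT": 2}
        assert report.recall["BL"] == pytest.approx(2 / 3)
        assert report.precision["BL"] == pytest.approx(1.0)
        assert report.recall["CPT"] == pytest.approx(1.0)
        assert report.precision["CPT"] == pytest.approx(2 / 3)
        assert report.accuracy == pytest.approx(4 / 5)
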