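"""Splitting, the clinical rule, LASSO selection, exhaustive search, SVM."""

import warnings

import numpy as np
import pytest

from lnradiomics.models import (
    TrainedModel,
    clinical_classify,
    exhaustive_search_select,
    lasso_cv_select,
    stratified_split,
    train_svm,
)


class TestStratifiedSplit:
    def test_study_sized_split_counts(self):
        labels = np.array([0] * 196 + [1] * 194)
        ids = [f"c{i}" for i in range(390)]
        plan = stratified_split(ids, labels, 0.8, seed=3)
        counts = plan.counts(dict(zip(ids, labels)))
        assert counts["train"] == {0: 157, 1: 155}
        assert counts["test"] == {0: 39, 1: 39}
        assert set(plan.train_ids) | set(plan.test_ids) == set(ids)
        assert not set(plan.train_ids) & set(plan.test_ids)

    def test_half_split_of_four(self):
        plan = stratified_split(["a", "b", "c", "d"], [0, 0, 1, 1], 0.5, seed=0)
        lab = {"a": 0, "b": 0, "c": 1, "d": 1}
        counts = plan.counts(lab)
        assert counts["train"] == {0: 1, 1: 1} and counts["test"] == {0: 1, 1: 1}

    def test_same_seed_identical_plan(self):
        labels = [0] * 10 + [1] * 10
        ids = list(range(20))
        p1 = stratified_split(ids, labels, 0.8, seed=7)
        p2 = stratified_split(ids, labels, 0.8, seed=7)
        assert p1.train_ids == p2.train_ids and p1.test_ids == p2.test_ids

    def test_missing_class_raises(self):
        with pytest.raises(ValueError):
            stratified_split([], [], 0.8, seed=0)


class TestClinicalRule:
    def test_boundary_is_strict(self):
        assert clinical_classify(10.0) == 0
        assert clinical_classify(10.1) == 1

    def test_metastatic_class_mean_flagged(self):
        assert clinical_classify(17.37) == 1

    def test_vectorized_and_validated(self):
        assert clinical_classify([5.0, 12.0]).tolist() == [0, 1]
        with pytest.raises(ValueError):
            clinical_classify(0.0)


class TestLassoSelect:
    def test_constant_labels_rejected(self):
        X = np.random.default_rng(0).normal(size=(30, 5))
        with pytest.raises(ValueError):
            lasso_cv_select(X, np.ones(30))

    def test_constant_columns_dropped_with_warning(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 3))
        X[:, 1] = 2.5
        y = (X[:, 0] > 0).astype(float)
        with pytest.warns(UserWarning, match="constant"):
            path = lasso_cv_select(X, y, ["a", "b", "c"], n_folds=5)
        assert path.dropped_constant == ["b"]
        assert "b" not in path.feature_names

    def test_null_labels_select_little(self):
        """With labels independent of X, median selected size over 50 seeds <= 2."""
        rng = np.random.default_rng(42)
        sizes = []
        for s in range(50):
            X = rng.normal(size=(100, 20))
            y = rng.integers(0, 2, size=100).astype(float)
            if y.min() == y.max():
                continue
            path = lasso_cv_select(X, y, n_folds=10, seed=s, n_lambdas=50)
            sizes.append(len(path.selected_features))
        assert np.median(sizes) <= 2

    def test_selection_consistency_with_strong_signal(self):
        """1 informative + 9 noise features: informative kept >= 95/100 runs."""
        hits = 0
        rng = np.random.default_rng(7)
        for s in range(100):
            X = rng.normal(size=(200, 10))
            y = (X[:, 0] + 0.3 * rng.normal(size=200) > 0).astype(float)
            path = lasso_cv_select(X, y, n_folds=10, seed=s, n_lambdas=50)
            hits += "x0" in path.selected_features
        assert hits >= 95

    def test_path_shape_and_df_monotonicity(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(80, 12))
        y = (X[:, 0] - X[:, 3] > 0).astype(float)
        path = lasso_cv_select(X, y, n_folds=5, n_lambdas=40)
        assert path.lambdas.shape == (40,)
        assert np.all(np.diff(path.lambdas) < 0)
        assert np.all(np.isfinite(path.cv_mse))
        # df grows (weakly, allowing small CV-noise wiggles) as lambda shrinks
        assert path.df[0] <= 1
        assert path.df[-1] >= path.df[0]
        sel_at_best = set(path.selected_features)
        best = int(np.argmin(path.cv_mse))
        nz = {path.feature_names[j]
              for j in np.flatnonzero(path.coefficients[best])}
        assert sel_at_best == nz

    def test_one_se_rule_is_sparser(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(120, 15))
        y = (X[:, 0] + 0.5 * X[:, 1] + rng.normal(size=120) > 0).astype(float)
        pmin = lasso_cv_select(X, y, n_folds=10, seed=0)
        p1se = lasso_cv_select(X, y, n_folds=10, seed=0, lambda_rule="1se")
        assert len(p1se.selected_features) <= len(pmin.selected_features)
        assert p1se.selected_lambda >= pmin.selected_lambda


class TestExhaustiveSearch:
    def test_single_candidate(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 1))
        y = (X[:, 0] > 0).astype(int)
        win, table = exhaustive_search_select(X, y, ["only"], n_folds=5)
        assert win == ("only",)

    def test_enumerates_all_63_subsets(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(60, 6))
        y = rng.integers(0, 2, 60)
        _, table = exhaustive_search_select(X, y, list("abcdef"), n_folds=5)
        assert len(table) == 63

    def test_short_axis_wins_when_only_it_carries_signal(self):
        """Reproduces the published selection outcome: {short_axis} alone."""
        from lnradiomics.models import encode_demographics

        rng = np.random.default_rng(11)
        records = []
        for i in range(240):
            lab = i % 2
            records.append({
                "age": float(rng.normal(62, 12)),
                "gender": "M" if rng.uniform() < 0.5 else "F",
                "histological_grade": "well" if rng.uniform() < 0.66 else "poor",
                "tumor_location": "left" if rng.uniform() < 0.47 else "right",
                # only the short axis separates the classes
                "short_axis": float(rng.normal(7.0 + 6.0 * lab, 1.0)),
                "long_axis": float(rng.normal(14.0, 5.0)),
                "label": lab,
            })
        X, names = encode_demographics(records)
        y = np.array([r["label"] for r in records])
        win, _ = exhaustive_search_select(X, y, names, n_folds=10, seed=0)
        assert win == ("short_axis",)


class TestTrainSVM:
    def test_separable_data_perfect_training_accuracy(self):
        X = np.vstack([np.random.default_rng(0).normal(0, 0.3, (20, 2)),
                       np.random.default_rng(1).normal(5, 0.3, (20, 2))])
        y = np.array([0] * 20 + [1] * 20)
        model = train_svm(X, y, n_folds=5)
        assert (model.predict(X) == y).all()

    def test_permuted_labels_chance_level(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(200, 4))
        y = rng.permutation([0, 1] * 100)
        model = train_svm(X, y, n_folds=10, seed=0)
        acc = 100.0 * (1.0 - model.cv_error)
        assert 40.0 <= acc <= 60.0

    def test_determinism_under_seed(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(60, 3))
        y = (X[:, 0] + 0.5 * rng.normal(size=60) > 0).astype(int)
        m1 = train_svm(X, y, n_folds=5, seed=9)
        m2 = train_svm(X, y, n_folds=5, seed=9)
        assert m1.hyperparameters == m2.hyperparameters
        assert np.allclose(m1.decision_scores(X), m2.decision_scores(X))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_svm(np.ones((10, 2)), np.ones(10, dtype=int))

    def test_test_labels_cannot_leak_into_fit(self):
        """Shuffling test labels must leave the trained model unchanged."""
        rng = np.random.default_rng(2)
        Xtr = rng.normal(size=(80, 3))
        ytr = (Xtr[:, 0] > 0).astype(int)
        Xte = rng.normal(size=(40, 3))
        model = train_svm(Xtr, ytr, n_folds=5, seed=1)
        scores_before = model.decision_scores(Xte)
        _ = rng.permutation(40)  # "shuffled test labels" never reach the API
        model2 = train_svm(Xtr, ytr, n_folds=5, seed=1)
        assert np.allclose(scores_before, model2.decision_scores(Xte))

    def test_json_serialization_roundtrip(self, tmp_path):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(50, 3))
        y = (X[:, 1] > 0).astype(int)
        model = train_svm(X, y, n_folds=5, seed=0)
        p = tmp_path / "model.json"
        model.save(p)
        loaded = TrainedModel.load(p)
        assert np.allclose(loaded.decision_scores(X), model.decision_scores(X),
                           atol=1e-10)
        assert (loaded.predict(X) == model.predict(X)).all()

    def test_clinical_model_serialization(self, tmp_path):
        model = TrainedModel(kind="clinical_threshold",
                             feature_names=("long_axis",), threshold_mm=10.0)
        p = tmp_path / "clin.json"
        model.save(p)
        loaded = TrainedModel.load(p)
        assert loaded.predict([[9.0], [11.0]]).tolist() == [0, 1]
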