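import numpy as np
import pandas as pd
import pytest

from mindwander.dataset_builder import Dataset
from mindwander.detection import (
    ModelSpec,
    compute_metrics,
    fold_standardize,
    nested_lopo_cv,
    permutation_null_kappa,
    shapley_importance,
    smote_oversample,
)


def make_dataset(rng, n_participants=6, rows_per=40, shift=3.0, rate=0.2, d=5):
    """Gaussian toy dataset with participant structure and class imbalance."""
    X, y, g = [], [], []
    for p in range(n_participants):
        offset = rng.normal(0, 0.3, d)
        labels = (rng.random(rows_per) < rate).astype(int)
        # guarantee both classes per participant
        labels[0], labels[1] = 0, 1
        rows = rng.normal(0, 1.0, (rows_per, d)) + offset
        rows[labels == 1, :2] += shift
        X.append(rows)
        y.append(labels)
        g.extend([f"P{p:02d}"] * rows_per)
    return Dataset(
        X=pd.DataFrame(np.vstack(X), columns=[f"f{i}" for i in range(d)]),
        y=np.concatenate(y),
        groups=np.asarray(g, dtype=object),
        feature_names=[f"f{i}" for i in range(d)],
    )


class TestSmote:
    def test_balanced_input_untouched(self, rng):
        X = rng.normal(size=(10, 3))
        y = np.array([0] * 5 + [1] * 5)
        X2, y2, synth = smote_oversample(X, y, seed=rng)
        np.testing.assert_array_equal(X2, X)
        assert not synth.any()

    def test_two_minority_points_interpolate_on_segment(self, rng):
        X = np.vstack([rng.normal(size=(8, 2)), [[0.0, 0.0], [1.0, 2.0]]])
        y = np.array([0] * 8 + [1] * 2)
        X2, y2, synth = smote_oversample(X, y, k=1, seed=rng)
        new = X2[synth]
        assert len(new) == 6
        # every synthetic point lies on the segment between the two minority rows
        frac = new[:, 0] / 1.0
        np.testing.assert_allclose(new[:, 1], 2.0 * frac, atol=1e-12)
        assert np.all((frac >= 0) & (frac <= 1))

    def test_classes_balanced_and_originals_preserved(self, rng):
        X = rng.normal(size=(50, 4))
        y = (rng.random(50) < 0.2).astype(int)
        y[:3] = 1
        X2, y2, synth = smote_oversample(X, y, seed=rng)
        assert (y2 == 0).sum() == (y2 == 1).sum()
        np.testing.assert_array_equal(X2[: len(X)], X)
        assert synth.sum() == len(X2) - len(X)

    def test_single_minority_point_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        y = np.array([0] * 9 + [1])
        with pytest.raises(ValueError, match="at least 2 minority"):
            smote_oversample(X, y, seed=rng)

    def test_large_k_reduced_with_warning(self, rng):
        X = rng.normal(size=(20, 2))
        y = np.array([0] * 17 + [1] * 3)
        with pytest.warns(UserWarning, match="reducing"):
            smote_oversample(X, y, k=5, seed=rng)


class TestFoldStandardize:
    def test_train_statistics_applied_to_test(self, rng):
        X_train = rng.normal(3.0, 2.0, (100, 4))
        X_test = X_train[:10] + 5.0
        Xt, Xe, scaler = fold_standardize(X_train, X_test)
        np.testing.assert_allclose(Xt.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(Xt.std(axis=0), 1.0, atol=1e-12)
        # shifted test fold does NOT standardize to (0, 1)
        assert np.all(np.abs(Xe.mean(axis=0)) > 1.0)

    def test_constant_feature_dropped(self, rng):
        X_train = np.column_stack([rng.normal(size=20), np.full(20, 7.0)])
        with pytest.warns(UserWarning, match="constant feature"):
            Xt, Xe, scaler = fold_standardize(X_train, X_train[:5])
        assert Xt.shape[1] == 1 and Xe.shape[1] == 1


class TestMetrics:
    def test_perfect_prediction(self):
        y = np.array([0] * 5 + [1] * 5)
        m = compute_metrics(y, y, scores=y.astype(float))
        assert m["accuracy"] == m["kappa"] == m["f1"] == m["auc"] == 1.0

    def test_hand_computed_confusion_table(self):
        """TP=3 FP=1 FN=2 TN=14 worked out by hand."""
        y_true = np.array([1] * 3 + [0] * 1 + [1] * 2 + [0] * 14)
        y_pred = np.array([1] * 3 + [1] * 1 + [0] * 2 + [0] * 14)
        m = compute_metrics(y_true, y_pred)
        assert m["accuracy"] == pytest.approx(17 / 20)
        # po=0.85, pe=0.25*0.2 + 0.75*0.8 = 0.65
        assert m["kappa"] == pytest.approx(0.2 / 0.35)
        # class1 F1 = 2/3, class0 F1 = 28/31; support weights 1/4, 3/4
        assert m["f1"] == pytest.approx(0.25 * (2 / 3) + 0.75 * (28 / 31))
        assert m["precision"] == pytest.approx(0.25 * 0.75 + 0.75 * (14 / 16))
        assert m["recall"] == pytest.approx(0.85)

    def test_all_positive_on_balanced_truth_has_zero_kappa(self):
        y_true = np.array([0] * 10 + [1] * 10)
        y_pred = np.ones(20, dtype=int)
        assert compute_metrics(y_true, y_pred)["kappa"] == 0.0

    def test_single_class_truth_gives_nan_auc(self):
        m = compute_metrics(np.zeros(5, int), np.zeros(5, int), scores=np.arange(5.0))
        assert np.isnan(m["auc"])

    def test_metrics_bounded(self, rng):
        for _ in range(20):
            y_true = (rng.random(30) < 0.3).astype(int)
            y_pred = (rng.random(30) < 0.5).astype(int)
            m = compute_metrics(y_true, y_pred, scores=rng.normal(size=30))
            for k in ("accuracy", "f1", "precision", "recall"):
                assert 0.0 <= m[k] <= 1.0
            assert -1.0 <= m["kappa"] <= 1.0


class TestNestedLopo:
    def test_one_fold_per_participant(self, rng):
        ds = make_dataset(rng)
        res = nested_lopo_cv(ds, ModelSpec("logistic", seed=0))
        assert len(res.folds) == 6
        assert sorted(f.participant for f in res.folds) == sorted(set(ds.groups))

    def test_separable_dataset_is_solved(self, rng):
        ds = make_dataset(rng, shift=8.0)
        res = nested_lopo_cv(ds, ModelSpec("logistic", seed=0))
        assert res.aggregate["f1"] == pytest.approx(1.0)
        assert res.aggregate["kappa"] == pytest.approx(1.0)

    def test_label_permutation_yields_chance_kappa(self, rng):
        ds = make_dataset(rng, shift=2.0)
        kappas = permutation_null_kappa(ds, ModelSpec("logistic", seed=0),
                                        n_permutations=5, seed=3)
        assert len(kappas) == 5
        assert abs(float(np.mean(kappas))) < 0.1

    def test_deterministic_under_seed(self, rng):
        ds = make_dataset(rng, shift=1.0)
        spec = ModelSpec("random_forest", grid=[{"n_estimators": 20, "max_depth": 3}], seed=5)
        a = nested_lopo_cv(ds, spec)
        b = nested_lopo_cv(ds, spec)
        assert a.aggregate == b.aggregate

    def test_too_few_participants_rejected(self, rng):
        ds = make_dataset(rng, n_participants=2)
        with pytest.raises(ValueError, match="at least 3 participants"):
            nested_lopo_cv(ds, ModelSpec("logistic"))

    def test_inner_grid_tunes_random_forest(self, rng):
        ds = make_dataset(rng, n_participants=4, rows_per=30, shift=2.0)
        spec = ModelSpec(
            "random_forest",
            grid=[{"n_estimators": 20, "max_depth": 2}, {"n_estimators": 20, "max_depth": 5}],
            seed=1,
        )
        res = nested_lopo_cv(ds, spec)
        assert all(
            f.chosen_params in spec.grid for f in res.folds
        )


class _LinearProbModel:
    """p(y=1|x) = sigmoid(w @ x + b); a transparent stand-in classifier."""

    def __init__(self, w, b=0.0):
        self.w = np.asarray(w, dtype=float)
        self.b = b

    def predict_proba(self, X):
        z = X @ self.w + self.b
        p = 1.0 / (1.0 + np.exp(-z))
        return np.column_stack([1 - p, p])


class TestShapley:
    def test_ignored_feature_gets_zero_attribution(self, rng):
        model = _LinearProbModel([1.0, 0.0, -2.0])
        X_bg = rng.normal(size=(50, 3))
        phi = shapley_importance(model, rng.normal(size=(4, 3)), X_bg,
                                 n_permutations=50, seed=0)
        assert np.abs(phi[:, 1]).max() < 1e-12

    def test_two_feature_closed_form(self, rng):
        """With one background row the exact Shapley value averages the two
        permutation orders; the sampler must converge to it."""
        model = _LinearProbModel([1.2, -0.7], b=0.3)
        b = np.array([[0.5, -0.4]])
        x = np.array([1.5, 1.0])

        def f(v):
            return model.predict_proba(np.atleast_2d(v))[0, 1]

        phi0 = 0.5 * (f([x[0], b[0, 1]]) - f(b[0])) + 0.5 * (f(x) - f([b[0, 0], x[1]]))
        phi1 = 0.5 * (f([b[0, 0], x[1]]) - f(b[0])) + 0.5 * (f(x) - f([x[0], b[0, 1]]))
        phi = shapley_importance(model, x[None, :], b, n_permutations=500, seed=1)
        assert phi[0, 0] == pytest.approx(phi0, abs=5e-3)
        assert phi[0, 1] == pytest.approx(phi1, abs=5e-3)

    def test_additivity_to_model_output(self, rng):
        model = _LinearProbModel([0.8, -1.1, 0.4])
        X_bg = rng.normal(size=(30, 3))
        x = np.array([[1.0, 0.5, -0.3]])
        phi = shapley_importance(model, x, X_bg, n_permutations=400, seed=2)
        fx = model.predict_proba(x)[0, 1]
        base = model.predict_proba(X_bg)[:, 1].mean()
        assert phi.sum() == pytest.approx(fx - base, abs=0.02)

    def test_symmetric_duplicated_features(self, rng):
        model = _LinearProbModel([1.0, 1.0])
        X_bg = np.zeros((1, 2))
        x = np.array([[2.0, 2.0]])
        phi = shapley_importance(model, x, X_bg, n_permutations=300, seed=3)
        assert phi[0, 0] == pytest.approx(phi[0, 1], abs=1e-9)

    def test_too_few_permutations_rejected(self, rng):
        model = _LinearProbModel([1.0])
        with pytest.raises(ValueError, match="at least 10"):
            shapley_importance(model, np.zeros((1, 1)), np.zeros((2, 1)),
                               n_permutations=5)
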