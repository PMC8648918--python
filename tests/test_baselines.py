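"""The four comparator classifiers and sequential forward selection."""

import numpy as np
import pytest

from mgmdhafs.baselines import (LogisticRegressionClassifier,
                                PoissonGlmClassifier, RbfSvmClassifier,
                                RbfnClassifier, sequential_forward_selection)
from mgmdhafs.data import FeatureTable
from mgmdhafs.metrics import metric_set
from mgmdhafs.validation import make_trainer
from conftest import make_labels


def table_from(X, kinds=None):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1:
        X = X.T
    names = [f"f{j}" for j in range(X.shape[1])]
    return FeatureTable([f"s{i}" for i in range(X.shape[0])], names, X,
                        kinds or ["continuous"] * X.shape[1])


def xor_dataset(per_corner=50, noise=0.15, seed=0):
    # balanced corners: no linear rule can beat chance
    rng = np.random.default_rng(seed)
    corners = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
    idx = np.repeat(np.arange(4), per_corner)
    X = corners[idx] + rng.normal(scale=noise, size=(len(idx), 2))
    y = (corners[idx, 0] != corners[idx, 1]).astype(int)
    return table_from(X), y


class TestLogisticRegression:
    def test_intercept_only_predicts_prevalence(self):
        table = FeatureTable([f"s{i}" for i in range(10)], [],
                             np.empty((10, 0)), [])
        y = make_labels(3, 7)
        res = LogisticRegressionClassifier(table, y).fit()
        assert np.allclose(res.predict_scores(table), 0.3, atol=1e-6)

    def test_separable_training_accuracy_with_finite_coefficients(self):
        y = make_labels(15, 15)
        table = table_from(y * 2.0 - 1.0)
        res = LogisticRegressionClassifier(table, y).fit()
        assert np.array_equal(res.predict(table), y)
        assert np.isfinite(res.coefficients).all()

    def test_xor_has_no_linear_separator(self):
        table, y = xor_dataset()
        res = LogisticRegressionClassifier(table, y).fit()
        assert abs(metric_set(y, res.predict(table)).mcc) <= 0.1

    def test_mean_predicted_probability_equals_prevalence(self, rng):
        X = rng.normal(size=(120, 4))
        y = (X[:, 0] + rng.normal(size=120) > 0.5).astype(int)
        res = LogisticRegressionClassifier(table_from(X), y).fit()
        assert res.predict_scores(table_from(X)).mean() == pytest.approx(y.mean(), abs=1e-4)

    def test_weight_threshold_drops_noise_features(self, rng):
        X = rng.normal(size=(400, 3))
        # noisy signal keeps the MLE finite and the coefficients moderate
        y = (X[:, 0] + rng.normal(size=400) > 0).astype(int)
        res = LogisticRegressionClassifier(table_from(X), y,
                                           weight_threshold=0.5).fit()
        assert 0 in res.kept_features
        assert res.coefficients[1] == 0.0 and res.coefficients[2] == 0.0


class TestPoissonGlm:
    def test_intercept_only_rate_is_label_mean(self):
        table = FeatureTable([f"s{i}" for i in range(10)], [],
                             np.empty((10, 0)), [])
        y = make_labels(3, 7)
        res = PoissonGlmClassifier(table, y).fit()
        assert np.allclose(res.predict_scores(table), 0.3, atol=1e-6)
        # 0.3 < 0.5 -> everything classified non-target
        assert res.predict(table).sum() == 0

    def test_rates_monotone_in_a_monotone_signal(self, rng):
        x = np.linspace(-2, 2, 80)
        y = (x + rng.normal(scale=0.3, size=80) > 0).astype(int)
        res = PoissonGlmClassifier(table_from(x), y).fit()
        rates = res.predict_scores(table_from(x))
        assert (np.diff(rates) >= -1e-12).all()


class TestRbfSvm:
    def test_xor_is_separable_with_rbf_kernel(self):
        table, y = xor_dataset()
        res = RbfSvmClassifier(table, y).fit(seed=0)
        assert metric_set(y, res.predict(table)).accuracy >= 0.95

    def test_wide_margin_generalizes_perfectly(self, rng):
        Xtr = np.r_[rng.normal(size=(40, 2)) + 4, rng.normal(size=(40, 2)) - 4]
        ytr = make_labels(40, 40)
        Xte = np.r_[rng.normal(size=(20, 2)) + 4, rng.normal(size=(20, 2)) - 4]
        yte = make_labels(20, 20)
        res = RbfSvmClassifier(table_from(Xtr), ytr).fit(seed=0)
        assert np.array_equal(res.predict(table_from(Xte)), yte)

    def test_decision_values_flip_sign_under_label_swap(self, rng):
        X = rng.normal(size=(60, 2))
        y = (X[:, 0] > 0).astype(int)
        grid = dict(c_grid=(1.0,), gamma_grid=(0.1,))
        a = RbfSvmClassifier(table_from(X), y, **grid).fit(seed=0)
        b = RbfSvmClassifier(table_from(X), 1 - y, **grid).fit(seed=0)
        # symmetric up to the SMO solver's numerical tolerance
        assert np.allclose(a.predict_scores(table_from(X)),
                           -b.predict_scores(table_from(X)), atol=0.02)

    def test_empty_grid_rejected(self, rng):
        X = rng.normal(size=(20, 2))
        y = make_labels(10, 10)
        with pytest.raises(ValueError):
            RbfSvmClassifier(table_from(X), y, c_grid=())


class TestRbfn:
    def test_two_blobs_with_two_prototypes(self, rng):
        Xtr = np.r_[rng.normal(size=(60, 2)) + 3, rng.normal(size=(60, 2)) - 3]
        ytr = make_labels(60, 60)
        Xte = np.r_[rng.normal(size=(30, 2)) + 3, rng.normal(size=(30, 2)) - 3]
        yte = make_labels(30, 30)
        res = RbfnClassifier(table_from(Xtr), ytr, n_centers=2).fit(seed=0)
        assert metric_set(yte, res.predict(table_from(Xte))).accuracy >= 0.95

    def test_single_center_has_no_discriminative_geometry(self, rng):
        X = rng.normal(size=(100, 2))
        y = (X[:, 0] > 0).astype(int)
        res = RbfnClassifier(table_from(X), y, n_centers=1).fit(seed=0)
        assert abs(metric_set(y, res.predict(table_from(X))).mcc) <= 0.2

    def test_seed_determinism_of_centers(self, rng):
        X = rng.normal(size=(50, 3))
        y = make_labels(25, 25)
        a = RbfnClassifier(table_from(X), y, n_centers=5).fit(seed=3)
        b = RbfnClassifier(table_from(X), y, n_centers=5).fit(seed=3)
        assert np.array_equal(a.centers, b.centers)

    def test_k_exceeding_samples_rejected(self, rng):
        X = rng.normal(size=(5, 2))
        with pytest.raises(ValueError):
            RbfnClassifier(table_from(X), make_labels(2, 3), n_centers=10)


class TestSequentialForwardSelection:
    def test_informative_feature_found_first(self):
        trainer = make_trainer(LogisticRegressionClassifier)
        first_hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(120, 6))
            y = (X[:, 2] > 0).astype(int)
            y[:3] = 1 - y[:3]  # mild label noise
            selected = sequential_forward_selection(
                trainer, table_from(X), y, max_features=1, seed=seed)
            first_hits += (selected[0] == 2)
        assert first_hits >= 18

    def test_identical_features_select_exactly_one(self, rng):
        x = rng.normal(size=100)
        X = np.column_stack([x, x, x])
        y = (x > 0).astype(int)
        trainer = make_trainer(LogisticRegressionClassifier)
        selected = sequential_forward_selection(trainer, table_from(X), y, seed=0)
        assert len(selected) == 1

    def test_max_features_cap(self, rng):
        X = rng.normal(size=(80, 5))
        y = ((X[:, 0] + X[:, 1] + X[:, 3]) > 0).astype(int)
        trainer = make_trainer(LogisticRegressionClassifier)
        selected = sequential_forward_selection(trainer, table_from(X), y,
                                                max_features=2, seed=0)
        assert len(selected) <= 2
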