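"""Linear classifiers: solvers, balancing, OVO decoding, feature reduction."""

import numpy as np
import pytest

from ribecho.errors import ConfigurationError, ContractError, DataError
from ribecho.linear import (LinearModel, OvoEnsemble, balance_classes,
                            fit_logistic, fit_svm, fit_ternary, predict,
                            rank_features, reduce_features)


def _clouds(rng, centers, n=40, spread=0.3):
    X, y = [], []
    for label, c in centers.items():
        X.append(rng.normal(loc=c, scale=spread, size=(n, len(c))))
        y += [label] * n
    return np.vstack(X), np.array(y)


class TestBalanceClasses:
    def test_undersamples_to_minority(self, rng):
        labels = np.array(["a"] * 20 + ["b"] * 80)
        idx = balance_classes(labels, seed=1)
        kept = labels[idx]
        assert (kept == "a").sum() == (kept == "b").sum() == 20

    def test_balanced_input_is_identity(self):
        labels = np.array(["a", "b"] * 10)
        np.testing.assert_array_equal(balance_classes(labels, seed=0),
                                      np.arange(20))

    def test_deterministic(self):
        labels = np.array(["a"] * 30 + ["b"] * 10)
        np.testing.assert_array_equal(balance_classes(labels, seed=7),
                                      balance_classes(labels, seed=7))

    def test_single_class_rejected(self):
        with pytest.raises(DataError):
            balance_classes(["a", "a", "a"])


class TestLogistic:
    def test_1d_separable_positive_weight(self):
        X = np.array([[-1.0], [-0.9], [0.9], [1.0]])
        y = np.array(["a", "a", "b", "b"])
        m = fit_logistic(X, y, reg_strength=1e-3,
                         feature_subset=("x",))
        assert m.weights[0] > 0
        assert list(predict(m, X)) == list(y)

    def test_uninformative_constant_feature_weight_vanishes(self, rng):
        X = np.column_stack([rng.normal(size=200),
                             np.full(200, 1.0)])
        y = np.where(X[:, 0] > 0, "b", "a")
        m = fit_logistic(X, y, feature_subset=("sig", "const"))
        assert abs(m.weights[1]) < abs(m.weights[0]) * 0.05

    def test_duplication_invariance(self, rng):
        X, y = _clouds(rng, {"a": (-1, 0), "b": (1, 0)}, n=30)
        m1 = fit_logistic(X, y, reg_strength=0.01, feature_subset=("u", "v"))
        m2 = fit_logistic(np.vstack([X, X]), np.concatenate([y, y]),
                          reg_strength=0.01, feature_subset=("u", "v"))
        np.testing.assert_allclose(m1.weights, m2.weights, atol=1e-5)

    def test_sample_order_invariance(self, rng):
        X, y = _clouds(rng, {"a": (-1, 1), "b": (1, -1)}, n=25)
        perm = rng.permutation(len(y))
        m1 = fit_logistic(X, y, feature_subset=("u", "v"))
        m2 = fit_logistic(X[perm], y[perm], feature_subset=("u", "v"))
        np.testing.assert_allclose(m1.weights, m2.weights, atol=1e-6)
        assert m1.bias == pytest.approx(m2.bias, abs=1e-6)

    def test_probability_calibration_at_optimum(self, rng):
        """Mean predicted probability matches the class-1 frequency."""
        X, y = _clouds(rng, {"a": (-0.5,), "b": (0.7,)}, n=60, spread=1.0)
        m = fit_logistic(X, y, feature_subset=("x",))
        p = 1.0 / (1.0 + np.exp(-m.score(X)))
        assert p.mean() == pytest.approx(np.mean(y == "b"), abs=0.02)

    def test_matches_sklearn_reference(self, rng):
        """Cross-check against an independent implementation."""
        sklearn = pytest.importorskip("sklearn.linear_model")
        X, y = _clouds(rng, {"a": (-0.4, 0.2), "b": (0.5, -0.3)}, n=50,
                       spread=0.8)
        m = fit_logistic(X, y, feature_subset=("u", "v"))
        # our lambda = 1/n mean-loss penalty equals sklearn C = 1 sum-loss
        ref = sklearn.LogisticRegression(C=1.0, tol=1e-10).fit(X, y == "b")
        np.testing.assert_allclose(m.weights, ref.coef_[0], atol=0.01)
        assert m.bias == pytest.approx(ref.intercept_[0], abs=0.01)


class TestSvm:
    def test_separated_clouds_zero_hinge(self, rng):
        X, y = _clouds(rng, {"a": (-2, -2), "b": (2, 2)}, n=30)
        m = fit_svm(X, y, feature_subset=("u", "v"))
        margin = np.where(y == "b", 1, -1) * m.score(X)
        assert np.mean(np.maximum(0, 1 - margin)) < 1e-4
        assert list(predict(m, X)) == list(y)

    def test_symmetric_points_boundary_at_origin(self):
        X = np.array([[-1.0], [-1.0], [1.0], [1.0]])
        y = np.array(["a", "a", "b", "b"])
        m = fit_svm(X, y, feature_subset=("x",))
        assert abs(m.bias / m.weights[0]) < 1e-4

    def test_box_constraint_keeps_separable_error_zero(self, rng):
        X, y = _clouds(rng, {"a": (-3,), "b": (3,)}, n=20)
        for c in (0.1, 1.0, 10.0):
            m = fit_svm(X, y, box_constraint=c, feature_subset=("x",))
            assert list(predict(m, X)) == list(y)


class TestTernary:
    def test_three_clouds_perfect_training(self, rng):
        X, y = _clouds(rng, {"a": (-2, 0), "b": (2, 0), "c": (0, 3)}, n=25)
        ens = fit_ternary(fit_logistic, X, y, feature_subset=("u", "v"))
        assert len(ens.members) == 3
        assert list(predict(ens, X)) == list(y)

    def test_majority_vote(self):
        def member(w, b, pair):
            return LinearModel(np.array(w), b, "logistic", 0.0, pair,
                               ("x",))
        # x=1: (a,b) votes b, (a,c) votes a, (b,c) votes b -> b wins 2:1
        ens = OvoEnsemble(("a", "b", "c"), [
            member([1.0], 0.0, ("a", "b")),
            member([-1.0], 0.0, ("a", "c")),
            member([-1.0], 0.0, ("b", "c")),
        ])
        assert predict(ens, [[1.0]])[0] == "b"

    def test_tie_broken_by_summed_margin(self):
        def member(w, b, pair):
            return LinearModel(np.array(w), b, "logistic", 0.0, pair, ("x",))
        # one vote each; (b,c) member has the largest |score| and votes c
        ens = OvoEnsemble(("a", "b", "c"), [
            member([1.0], 0.0, ("a", "b")),    # score 1 -> b
            member([-1.0], 0.0, ("a", "c")),   # score -1 -> a
            member([-5.0], 0.0, ("b", "c")),   # score -5 -> ... c? sign<0 -> b
        ])
        # scores at x=1: b gets 1 + 5 = 6, a gets 1 -> b
        assert predict(ens, [[1.0]])[0] == "b"

    def test_degenerate_zero_model_votes_positive(self):
        m = LinearModel(np.zeros(1), 0.0, "logistic", 0.0, ("a", "b"), ("x",))
        assert predict(m, [[123.0]])[0] == "b"

    def test_schema_width_mismatch_rejected(self, rng):
        X, y = _clouds(rng, {"a": (-1, 0), "b": (1, 0)}, n=10)
        m = fit_logistic(X, y, feature_subset=("u", "v"))
        with pytest.raises(ContractError):
            predict(m, np.zeros((3, 5)))


class TestReduceFeatures:
    def test_full_k_is_identity_subset(self, rng):
        X, y = _clouds(rng, {"a": (-1, 0, 0), "b": (1, 0, 0)}, n=20)
        names = ("f1", "f2", "f3")
        m = reduce_features(X, y, 3, fit_logistic, feature_names=names)
        assert m.feature_subset == names

    def test_single_informative_feature_selected(self, rng):
        signal = rng.normal(size=120)
        X = np.column_stack([rng.normal(size=120), signal,
                             rng.normal(size=120)])
        y = np.where(signal > 0, "b", "a")
        names = ("noise1", "signal", "noise2")
        m = reduce_features(X, y, 1, fit_logistic, feature_names=names)
        assert m.feature_subset == ("signal",)
        assert np.mean(predict(m, X[:, [1]]) == y) > 0.95

    def test_ranking_prefix_nested(self, rng):
        X, y = _clouds(rng, {"a": tuple([-1] * 6), "b": tuple([1] * 6)}, n=20)
        names = tuple(f"f{i}" for i in range(6))
        order = rank_features(X, y, names)
        assert set(order[:3]).issubset(set(order[:5]))

    def test_k_out_of_range(self, rng):
        X, y = _clouds(rng, {"a": (-1,), "b": (1,)}, n=10)
        with pytest.raises(ConfigurationError):
            reduce_features(X, y, 5, fit_logistic, feature_names=("x",))
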