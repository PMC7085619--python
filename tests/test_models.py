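"""Classifier suite: network primitives, oracles and the uniform contract."""
import numpy as np
import pytest
from scipy.optimize import minimize

from cyclesense import models as md


def blobs(rng, n=30, d=2, sep=10.0):
    X = np.vstack([rng.normal(0.0, 1.0, (n, d)), rng.normal(sep, 1.0, (n, d))])
    y = np.array(["a"] * n + ["b"] * n)
    return X, y


class TestNetworkForward:
    def test_zero_parameters_give_uniform_probabilities(self):
        p = md.NetworkParams(W1=np.zeros((3, 4)), b1=np.zeros(3),
                             W2=np.zeros((2, 3)), b2=np.zeros(2))
        out = md.nn_forward(p, np.random.default_rng(0).normal(size=(4, 7)))
        np.testing.assert_allclose(out, 0.5)

    def test_softmax_shift_invariance(self, rng):
        p = md.NetworkParams(W1=rng.normal(size=(5, 3)), b1=rng.normal(size=5),
                             W2=rng.normal(size=(4, 5)), b2=rng.normal(size=4))
        shifted = md.NetworkParams(W1=p.W1, b1=p.b1, W2=p.W2,
                                   b2=p.b2 + 17.3)  # constant added to logits
        P = rng.normal(size=(3, 6))
        np.testing.assert_allclose(md.nn_forward(p, P),
                                   md.nn_forward(shifted, P), atol=1e-12)

    def test_columns_sum_to_one(self, rng):
        p = md.nn_init(5, 10, 4, seed=1)
        out = md.nn_forward(p, rng.normal(size=(5, 8)))
        np.testing.assert_allclose(out.sum(axis=0), 1.0, atol=1e-12)
        assert ((out > 0) & (out < 1)).all()

    def test_shape_mismatch_rejected(self):
        p = md.nn_init(5, 4, 2, seed=0)
        with pytest.raises(ValueError):
            md.nn_forward(p, np.zeros((3, 4)))


class TestNetworkTraining:
    def test_analytic_gradient_matches_central_differences(self, rng):
        """Backprop gradients agree with finite differences to 1e-6 relative."""
        P = rng.normal(size=(3, 5))
        T = np.zeros((2, 5))
        T[rng.integers(0, 2, 5), np.arange(5)] = 1.0
        params = md.nn_init(3, 4, 2, seed=3, scale=0.7)
        _, grads = md.nn_loss_and_grads(params, P, T)
        eps = 1e-6
        for name in ("W1", "b1", "W2", "b2"):
            arr = getattr(params, name)
            g = getattr(grads, name)
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                ix = it.multi_index
                orig = arr[ix]
                arr[ix] = orig + eps
                lp, _ = md.nn_loss_and_grads(params, P, T)
                arr[ix] = orig - eps
                lm, _ = md.nn_loss_and_grads(params, P, T)
                arr[ix] = orig
                fd = (lp - lm) / (2 * eps)
                assert g[ix] == pytest.approx(fd, rel=1e-6, abs=1e-9), (name, ix)

    def test_separable_blobs_reach_perfect_training_accuracy(self, rng):
        X, y = blobs(rng, n=20, sep=10.0)
        clf = md.NeuralNetClassifier(hidden=4, seed=0).fit(X, y)
        assert np.mean(clf.predict(X) == y) == 1.0

    def test_loss_history_is_non_increasing(self, rng):
        X, y = blobs(rng, n=15, sep=3.0)
        clf = md.NeuralNetClassifier(hidden=6, seed=2).fit(X, y)
        h = np.array(clf.history_)
        assert (np.diff(h) <= 1e-15).all()

    def test_seeded_training_is_reproducible(self, rng):
        X, y = blobs(rng, n=12, sep=4.0)
        a = md.NeuralNetClassifier(seed=5).fit(X, y)
        b = md.NeuralNetClassifier(seed=5).fit(X, y)
        np.testing.assert_array_equal(a.params_.W1, b.params_.W1)
        np.testing.assert_array_equal(a.params_.b2, b.params_.b2)

    def test_single_class_targets_rejected(self):
        with pytest.raises(ValueError):
            md.NeuralNetClassifier().fit(np.zeros((5, 2)), np.array(["a"] * 5))


class TestGaussianBayes:
    def _fit_1d(self, priors="uniform"):
        # classes with exactly mean 0 / 10 and population variance 1
        X = np.array([[-1.0], [1.0], [9.0], [11.0]])
        y = np.array(["a", "a", "b", "b"])
        return md.GaussianBayesClassifier(priors=priors).fit(X, y)

    def test_midpoint_is_equivocal(self):
        proba = self._fit_1d().predict_proba(np.array([[5.0]]))
        np.testing.assert_allclose(proba, [[0.5, 0.5]], atol=1e-12)

    def test_near_class_posterior_matches_density_ratio(self):
        # at x = 0 the likelihood ratio is e^0 : e^-50
        proba = self._fit_1d().predict_proba(np.array([[0.0]]))
        assert proba[0, 0] > 0.999
        assert proba[0, 1] == pytest.approx(np.exp(-50.0), rel=1e-6)

    def test_doubled_prior_shifts_posterior_by_bayes_rule(self):
        proba = self._fit_1d(priors={"a": 2.0, "b": 1.0}).predict_proba(
            np.array([[5.0]]))
        np.testing.assert_allclose(proba, [[2 / 3, 1 / 3]], atol=1e-12)

    def test_posteriors_sum_to_one(self, rng):
        X, y = blobs(rng, n=10, d=3, sep=2.0)
        proba = md.bayes_fit_predict(X, y, rng.normal(size=(6, 3)))
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-12)


def knn_oracle(train_X, train_y, query, k):
    """Exhaustive sort-all-distances reference with the documented tie rules."""
    d = np.sqrt(((train_X - query) ** 2).sum(axis=1))
    idx = np.argsort(d, kind="stable")[:k]
    labels, dists = train_y[idx], d[idx]
    best = sorted(set(labels.tolist()),
                  key=lambda c: (-(labels == c).sum(),
                                 dists[labels == c].sum(), c))
    return best[0]


class TestKNN:
    def test_query_on_training_point_with_k1(self, rng):
        X, y = blobs(rng, n=10)
        clf = md.KNNClassifier(k=1).fit(X, y)
        assert clf.predict(X[3:4])[0] == y[3]

    def test_k_equals_n_returns_global_majority(self, rng):
        X = rng.normal(size=(9, 2))
        y = np.array(["a"] * 5 + ["b"] * 4)
        clf = md.KNNClassifier(k=9, standardize=False).fit(X, y)
        assert (clf.predict(rng.normal(size=(6, 2))) == "a").all()

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_bruteforce_oracle_on_random_problems(self, seed):
        """50 random 40-point 2-class problems, k = 5, vs the exhaustive
        distance-sort oracle."""
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(40, 2))
        y = rng.choice(["a", "b"], size=40)
        if len(set(y)) < 2:
            y[0] = "a" if y[1] == "b" else "b"
        clf = md.KNNClassifier(k=5, standardize=False).fit(X, y)
        queries = rng.normal(size=(10, 2))
        got = clf.predict(queries)
        want = [knn_oracle(X, y, q, 5) for q in queries]
        np.testing.assert_array_equal(got, want)

    def test_k_larger_than_training_rejected(self, rng):
        with pytest.raises(ValueError):
            md.KNNClassifier(k=10).fit(rng.normal(size=(5, 2)),
                                       np.array(list("ababa")))


def svm_dual_oracle(Xa, ysign, C):
    """Generic box-constrained QP solve of the bias-augmented SVM dual."""
    Q = (ysign[:, None] * Xa) @ (ysign[:, None] * Xa).T
    fun = lambda a: 0.5 * a @ Q @ a - a.sum()
    jac = lambda a: Q @ a - 1.0
    n = Xa.shape[0]
    res = minimize(fun, np.full(n, C / 2), jac=jac, method="SLSQP",
                   bounds=[(0.0, C)] * n,
                   options={"maxiter": 500, "ftol": 1e-12})
    return -res.fun


class TestLinearSVM:
    def test_two_point_boundary_at_origin(self):
        X = np.array([[-1.0], [1.0]])
        y = np.array(["neg", "pos"])
        clf = md.LinearSVMClassifier().fit(X, y)
        assert clf.predict(np.array([[-2.0]]))[0] == "neg"
        assert clf.predict(np.array([[2.0]]))[0] == "pos"
        assert abs(clf.decision_function(np.array([[0.0]]))[0]) < 1e-8

    def test_separable_blobs_reach_perfect_training_accuracy(self, rng):
        X, y = blobs(rng, n=20, sep=8.0)
        assert (md.svm_fit_predict(X, y, X) == y).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_dual_objective_matches_qp_oracle(self, seed):
        """Coordinate-ascent dual objective within 1e-4 of a dense QP solve
        on 20-point problems."""
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(20, 2))
        y = np.where(rng.random(20) > 0.5, "p", "n")
        if len(set(y.tolist())) < 2:
            y[0] = "p" if y[1] == "n" else "n"
        clf = md.LinearSVMClassifier(C=1.0).fit(X, y)
        Xa = np.hstack([clf._std.transform(X), np.ones((20, 1))])
        want = svm_dual_oracle(Xa, clf._ysign, C=1.0)
        assert clf.dual_objective() == pytest.approx(want, abs=1e-4)

    def test_multiclass_rejected(self, rng):
        X = rng.normal(size=(9, 2))
        y = np.array(list("abcabcabc"))
        with pytest.raises(ValueError, match="binary"):
            md.LinearSVMClassifier().fit(X, y)


class TestUniformContract:
    @pytest.mark.parametrize("kind", ["nn", "bayes", "knn", "svm"])
    def test_deterministic_predictions(self, kind, rng):
        X, y = blobs(rng, n=15, sep=3.0)
        Xq = rng.normal(1.5, 2.0, size=(20, 2))
        kw = {"seed": 0} if kind == "nn" else {}
        a = md.make_classifier(kind, **kw).fit(X, y).predict(Xq)
        b = md.make_classifier(kind, **kw).fit(X, y).predict(Xq)
        np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize("kind", ["nn", "bayes"])
    def test_probabilistic_outputs_normalized(self, kind, rng):
        X, y = blobs(rng, n=15, sep=3.0)
        kw = {"seed": 0} if kind == "nn" else {}
        proba = md.make_classifier(kind, **kw).fit(X, y).predict_proba(
            rng.normal(size=(8, 2)))
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-12)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            md.make_classifier("forest")
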