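"""From-scratch classifier suite with a uniform fit/predict contract.

Four families, mirroring the study's comparison: a two-layer neural network
(sigmoid hidden layer, softmax output), Gaussian naive Bayes, k-nearest
neighbours and a soft-margin linear SVM.  All are deterministic given
(data, seed) and operate on samples-by-features arrays.

The network is the study's model: for a pattern matrix P (R x Q),

    A1 = sigmoid(W1 P + b1)          (S1 x Q)
    A2 = softmax(W2 A1 + b2)         (S2 x Q, column-wise)

trained here by full-batch gradient descent on the cross-entropy with a
step-halving line search, so the training loss is non-increasing by
construction.  The study states the architecture but not the training
scheme; this is the simplest scheme satisfying the probabilistic output
contract.

k-NN, SVM and the network standardize features internally (z-score from
the training data) because the feature units are mixed (percent vs bpm);
naive Bayes is scale-equivariant and uses raw features.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "NetworkParams",
    "nn_init",
    "nn_forward",
    "nn_loss_and_grads",
    "nn_train",
    "NeuralNetClassifier",
    "GaussianBayesClassifier",
    "KNNClassifier",
    "LinearSVMClassifier",
    "make_classifier",
    "bayes_fit_predict",
    "knn_predict",
    "svm_fit_predict",
]


# ---------------------------------------------------------------------------
# two-layer network primitives (matrix convention: P is R x Q, columns = samples)


@dataclass
class NetworkParams:
    """Weights and biases of the two-layer network."""

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray

    def __post_init__(self) -> None:
        self.W1 = np.atleast_2d(np.asarray(self.W1, dtype=float))
        self.W2 = np.atleast_2d(np.asarray(self.W2, dtype=float))
        self.b1 = np.asarray(self.b1, dtype=float).reshape(-1, 1)
        self.b2 = np.asarray(self.b2, dtype=float).reshape(-1, 1)
        s1, r = self.W1.shape
        s2, s1b = self.W2.shape
        if s1b != s1 or self.b1.shape[0] != s1 or self.b2.shape[0] != s2:
            raise ValueError("inconsistent network shapes")
        for a in (self.W1, self.b1, self.W2, self.b2):
            if not np.all(np.isfinite(a)):
                raise ValueError("network parameters must be finite")

    @property
    def shapes(self) -> tuple[int, int, int]:
        """(R inputs, S1 hidden, S2 outputs)."""
        return self.W1.shape[1], self.W1.shape[0], self.W2.shape[0]


def nn_init(n_inputs: int, hidden: int, n_outputs: int, seed: int,
            scale: float = 0.5) -> NetworkParams:
    """Small-uniform seeded initialization."""
    rng = np.random.default_rng(seed)
    return NetworkParams(
        W1=rng.uniform(-scale, scale, (hidden, n_inputs)),
        b1=rng.uniform(-scale, scale, hidden),
        W2=rng.uniform(-scale, scale, (n_outputs, hidden)),
        b2=rng.uniform(-scale, scale, n_outputs),
    )


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _softmax_columns(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=0, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=0, keepdims=True)


def nn_forward(params: NetworkParams, P: np.ndarray) -> np.ndarray:
    """Forward pass: class probabilities A2 (S2 x Q); columns sum to 1."""
    P = np.atleast_2d(np.asarray(P, dtype=float))
    if P.shape[0] != params.W1.shape[1]:
        raise ValueError(
            f"P has {P.shape[0]} feature rows, network expects {params.W1.shape[1]}"
        )
    A1 = _sigmoid(params.W1 @ P + params.b1)
    return _softmax_columns(params.W2 @ A1 + params.b2)


def nn_loss_and_grads(
    params: NetworkParams, P: np.ndarray, T: np.ndarray
) -> tuple[float, NetworkParams]:
    """Mean cross-entropy and its analytic gradients (as a params-shaped pack)."""
    P = np.atleast_2d(np.asarray(P, dtype=float))
    T = np.atleast_2d(np.asarray(T, dtype=float))
    q = P.shape[1]
    A1 = _sigmoid(params.W1 @ P + params.b1)
    A2 = _softmax_columns(params.W2 @ A1 + params.b2)
    loss = float(-np.sum(T * np.log(np.clip(A2, 1e-300, None))) / q)
    dZ2 = (A2 - T) / q
    dW2 = dZ2 @ A1.T
    db2 = dZ2.sum(axis=1)
    dZ1 = (params.W2.T @ dZ2) * A1 * (1.0 - A1)
    dW1 = dZ1 @ P.T
    db1 = dZ1.sum(axis=1)
    return loss, NetworkParams(W1=dW1, b1=db1, W2=dW2, b2=db2)


def nn_train(
    P: np.ndarray,
    T: np.ndarray,
    hidden: int = 10,
    epochs: int = 150,
    lr: float = 1.0,
    seed: int = 0,
    tol: float = 1e-8,
) -> tuple[NetworkParams, list[float]]:
    """Full-batch gradient descent on the cross-entropy.

    A step-halving line search rejects any step that would increase the
    loss, so the recorded loss sequence is non-increasing.  Training stops
    early when the relative improvement falls below ``tol``.

    Returns the fitted parameters and the per-epoch loss history.
    """
    P = np.atleast_2d(np.asarray(P, dtype=float))
    T = np.atleast_2d(np.asarray(T, dtype=float))
    if P.shape[1] != T.shape[1]:
        raise ValueError("P and T must agree in the number of columns")
    if T.shape[0] < 2 or np.any(T.sum(axis=1) == T.shape[1]):
        raise ValueError("degenerate target matrix: need at least two classes")
    params = nn_init(P.shape[0], hidden, T.shape[0], seed)
    loss, grads = nn_loss_and_grads(params, P, T)
    history = [loss]
    step = lr
    for _ in range(epochs):
        for _try in range(40):
            cand = NetworkParams(
                W1=params.W1 - step * grads.W1,
                b1=params.b1 - step * grads.b1,
                W2=params.W2 - step * grads.W2,
                b2=params.b2 - step * grads.b2,
            )
            new_loss, new_grads = nn_loss_and_grads(cand, P, T)
            if new_loss <= loss:
                break
            step *= 0.5
        else:
            break  # no descent step found: converged
        params, grads = cand, new_grads
        improved = loss - new_loss
        loss = new_loss
        history.append(loss)
        step = min(step * 1.25, 10.0 * lr)
        if improved < tol * max(1.0, abs(loss)):
            break
    return params, history


# ---------------------------------------------------------------------------
# uniform classifier contract


class _Standardizer:
    def fit(self, X: np.ndarray) -> "_Standardizer":
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        self.scale_ = np.where(sd > 0, sd, 1.0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean_) / self.scale_


def _check_xy(X, y):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    if X.shape[0] != y.size:
        raise ValueError("X and y disagree in sample count")
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    return X, y


class NeuralNetClassifier:
    """Two-layer sigmoid/softmax network behind the uniform contract."""

    kind = "nn"

    def __init__(self, hidden: int = 10, epochs: int = 150, lr: float = 1.0,
                 seed: int = 0):
        self.hidden, self.epochs, self.lr, self.seed = hidden, epochs, lr, seed

    def fit(self, X: np.ndarray, y: np.ndarray) -> "NeuralNetClassifier":
        X, y = _check_xy(X, y)
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ValueError("need at least two classes")
        self._std = _Standardizer().fit(X)
        Xs = self._std.transform(X)
        T = (y[None, :] == self.classes_[:, None]).astype(float)
        self.params_, self.history_ = nn_train(
            Xs.T, T, hidden=self.hidden, epochs=self.epochs, lr=self.lr,
            seed=self.seed,
        )
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return nn_forward(self.params_, self._std.transform(X).T).T

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


class GaussianBayesClassifier:
    """Naive Bayes with per-feature Gaussian densities.

    Equal class priors by default (``priors="uniform"``); ``"empirical"``
    uses training frequencies.  A variance floor guards zero-variance
    features.
    """

    kind = "bayes"

    def __init__(self, priors: str | dict = "uniform", var_floor: float = 1e-9):
        self.priors, self.var_floor = priors, var_floor

    def fit(self, X: np.ndarray, y: np.ndarray) -> "GaussianBayesClassifier":
        X, y = _check_xy(X, y)
        self.classes_ = np.unique(y)
        means, variances, priors = [], [], []
        floor = self.var_floor * max(float(X.var(axis=0).max()), 1.0)
        for c in self.classes_:
            sub = X[y == c]
            if sub.shape[0] < 2:
                raise ValueError(f"class {c!r} has fewer than 2 training samples")
            means.append(sub.mean(axis=0))
            variances.append(np.maximum(sub.var(axis=0, ddof=0), floor))
            priors.append(sub.shape[0] / X.shape[0])
        self.means_ = np.array(means)
        self.vars_ = np.array(variances)
        if self.priors == "uniform":
            self.priors_ = np.full(self.classes_.size, 1.0 / self.classes_.size)
        elif self.priors == "empirical":
            self.priors_ = np.array(priors)
        else:
            self.priors_ = np.array([self.priors[c] for c in self.classes_], float)
            self.priors_ = self.priors_ / self.priors_.sum()
        return self

    def _log_posteriors(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        ll = -0.5 * (
            ((X[:, None, :] - self.means_[None]) ** 2 / self.vars_[None]).sum(axis=2)
            + np.log(2.0 * np.pi * self.vars_).sum(axis=1)[None]
        )
        return ll + np.log(self.priors_)[None]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        lp = self._log_posteriors(X)
        lp -= lp.max(axis=1, keepdims=True)
        p = np.exp(lp)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self._log_posteriors(X), axis=1)]


class KNNClassifier:
    """k nearest neighbours with deterministic tie-breaking.

    Majority vote over the k Euclidean-nearest training points; vote ties
    are broken by the smallest summed neighbour distance, then by the
    lowest class label.
    """

    kind = "knn"

    def __init__(self, k: int = 5, standardize: bool = True):
        if k < 1:
            raise ValueError("k must be >= 1")
        self.k, self.standardize = k, standardize

    def fit(self, X: np.ndarray, y: np.ndarray) -> "KNNClassifier":
        X, y = _check_xy(X, y)
        if self.k > X.shape[0]:
            raise ValueError(f"k={self.k} exceeds training size {X.shape[0]}")
        self._std = _Standardizer().fit(X) if self.standardize else None
        self._X = self._std.transform(X) if self._std else X
        self._y = y
        self.classes_ = np.unique(y)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self._std:
            X = self._std.transform(X)
        d2 = ((X[:, None, :] - self._X[None]) ** 2).sum(axis=2)
        out = []
        order = np.argsort(d2, axis=1, kind="stable")[:, : self.k]
        for row, idx in zip(d2, order):
            labels = self._y[idx]
            dists = np.sqrt(row[idx])
            cand = sorted(
                set(labels.tolist()),
                key=lambda c: (
                    -(labels == c).sum(),          # most votes
                    dists[labels == c].sum(),      # then closest in total
                    c,                             # then lowest label
                ),
            )
            out.append(cand[0])
        return np.array(out)


class LinearSVMClassifier:
    """Soft-margin linear SVM (binary) solved by dual coordinate ascent.

    The bias is folded into the weight vector through a constant feature,
    leaving a box-constrained dual that plain coordinate ascent solves
    deterministically.  C = 1 by default.
    """

    kind = "svm"

    def __init__(self, C: float = 1.0, max_sweeps: int = 1000, tol: float = 1e-10):
        if C <= 0:
            raise ValueError("C must be positive")
        self.C, self.max_sweeps, self.tol = C, max_sweeps, tol

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LinearSVMClassifier":
        X, y = _check_xy(X, y)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError(
                f"linear SVM handles binary tasks; got {self.classes_.size} classes"
            )
        self._std = _Standardizer().fit(X)
        Xa = np.hstack([self._std.transform(X), np.ones((X.shape[0], 1))])
        ysign = np.where(y == self.classes_[1], 1.0, -1.0)
        n = Xa.shape[0]
        diag = (Xa * Xa).sum(axis=1)
        alpha = np.zeros(n)
        w = np.zeros(Xa.shape[1])
        for _ in range(self.max_sweeps):
            biggest = 0.0
            for i in range(n):
                g = ysign[i] * (w @ Xa[i]) - 1.0
                a_new = min(max(alpha[i] - g / diag[i], 0.0), self.C)
                delta = a_new - alpha[i]
                if delta != 0.0:
                    w += delta * ysign[i] * Xa[i]
                    alpha[i] = a_new
                    biggest = max(biggest, abs(delta))
            if biggest < self.tol:
                break
        self.alpha_, self.w_ = alpha, w
        self._ysign = ysign
        return self

    def dual_objective(self) -> float:
        """sum(alpha) - 0.5 ||w||^2 of the bias-augmented dual."""
        return float(self.alpha_.sum() - 0.5 * self.w_ @ self.w_)

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Xa = np.hstack([self._std.transform(X), np.ones((X.shape[0], 1))])
        return Xa @ self.w_

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.where(self.decision_function(X) >= 0,
                        self.classes_[1], self.classes_[0])


_KINDS = {
    "nn": NeuralNetClassifier,
    "bayes": GaussianBayesClassifier,
    "knn": KNNClassifier,
    "svm": LinearSVMClassifier,
}


def make_classifier(kind: str, **kwargs):
    """Instantiate one of the four classifier families by name."""
    try:
        cls = _KINDS[kind]
    except KeyError:
        raise ValueError(f"unknown classifier kind {kind!r}; choose from {sorted(_KINDS)}")
    return cls(**kwargs)


# ---------------------------------------------------------------------------
# functional one-shot helpers


def bayes_fit_predict(train_X, train_y, test_X, priors="uniform") -> np.ndarray:
    """Posterior class probabilities of ``test_X`` under Gaussian naive Bayes."""
    return GaussianBayesClassifier(priors=priors).fit(train_X, train_y).predict_proba(test_X)


def knn_predict(train_X, train_y, test_X, k: int = 5) -> np.ndarray:
    """k-NN labels for ``test_X``."""
    return KNNClassifier(k=k).fit(train_X, train_y).predict(test_X)


def svm_fit_predict(train_X, train_y, test_X, C: float = 1.0) -> np.ndarray:
    """Linear soft-margin SVM labels for ``test_X``."""
    return LinearSVMClassifier(C=C).fit(train_X, train_y).predict(test_X)
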