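"""KNN and extreme-learning-machine baselines for spectral classification.

The KNN side reproduces the classical chemometric recipe: a per-band
transform fitted on training data only (mean centering, min-max scaling or a
log transform), one of three distances (variance-standardized Euclidean,
correlation, shrunk-covariance Mahalanobis), majority voting with explicit
tie-breaking, and a full k x transform x distance grid sweep.

The ELM is a single-hidden-layer network whose input weights and biases are
drawn once at random (uniform in [-1, 1]); only the output layer is solved,
in closed form, as the minimum-norm least-squares map from the sigmoid
hidden activations to one-hot targets.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .types import SpectrumSet

__all__ = [
    "SpectrumTransform",
    "KNNVarietyClassifier",
    "ELMClassifier",
    "knn_predict",
    "knn_grid_search",
    "elm_train",
    "elm_predict",
]

TRANSFORMS = ("none", "mean_center", "min_max", "log")
DISTANCES = ("standardized_euclidean", "correlation", "mahalanobis")

_LOG_EPS = 1e-6


class SpectrumTransform(BaseEstimator, TransformerMixin):
    """Per-band transform with strict fit/apply separation.

    ``mean_center`` subtracts the training mean per band; ``min_max`` rescales
    each band to the training [min, max]; ``log`` is the stateless map
    ``log(x + 1e-6)`` (reflectance lives in (0, 1+]).
    """

    def __init__(self, kind: str = "none"):
        self.kind = kind

    def fit(self, X, y=None):
        if self.kind not in TRANSFORMS:
            raise ValueError(f"kind must be one of {TRANSFORMS}")
        X = np.asarray(X, dtype=float)
        if self.kind == "mean_center":
            self.mean_ = X.mean(axis=0)
        elif self.kind == "min_max":
            self.min_ = X.min(axis=0)
            span = X.max(axis=0) - self.min_
            span[span == 0] = 1.0
            self.span_ = span
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "n_features_in_")
        X = np.asarray(X, dtype=float)
        if self.kind == "none":
            return X.copy()
        if self.kind == "mean_center":
            return X - self.mean_
        if self.kind == "min_max":
            return (X - self.min_) / self.span_
        # reflectance is nominally in (0, 1+]; clip shields the log from the
        # rare slightly-negative values noise can produce
        return np.log(np.maximum(X, 0.0) + _LOG_EPS)


def _shrunk_covariance(X: np.ndarray, shrinkage: float | None) -> tuple[np.ndarray, float]:
    """Sample covariance shrunk toward its own diagonal.

    With 320 bands and at most a couple of thousand training rows the sample
    covariance is ill-conditioned; shrinkage ``(1 - l) S + l diag(S)`` keeps
    it positive definite. ``shrinkage=None`` picks l analytically with the
    Ledoit-Wolf estimator; full shrinkage (l = 1) reduces the Mahalanobis
    distance to variance-standardized Euclidean.
    """
    S = np.cov(X, rowvar=False)
    if shrinkage is None:
        from sklearn.covariance import LedoitWolf

        shrinkage = float(LedoitWolf().fit(X).shrinkage_)
    if not 0.0 <= shrinkage <= 1.0:
        raise ValueError("cov_shrinkage must lie in [0, 1]")
    target = np.diag(np.diag(S))
    C = (1.0 - shrinkage) * S + shrinkage * target
    # numerical jitter so Cholesky/inverse succeed even at shrinkage 0
    C += 1e-10 * np.trace(C) / C.shape[0] * np.eye(C.shape[0])
    return C, shrinkage


def _pairwise(test: np.ndarray, train: np.ndarray, kind: str,
              cov_shrinkage: float | None) -> np.ndarray:
    if kind == "standardized_euclidean":
        var = train.var(axis=0, ddof=1)
        var[var == 0] = 1.0
        return cdist(test, train, metric="seuclidean", V=var)
    if kind == "correlation":
        return cdist(test, train, metric="correlation")
    if kind == "mahalanobis":
        C, _ = _shrunk_covariance(train, cov_shrinkage)
        # whiten with the Cholesky factor: d_M(x, y) = ||L^-1 (x - y)||_2,
        # which turns the quadratic-form metric into a plain Euclidean cdist
        from scipy.linalg import cholesky, solve_triangular

        L = cholesky(C, lower=True)
        tw = solve_triangular(L, test.T, lower=True).T
        rw = solve_triangular(L, train.T, lower=True).T
        return cdist(tw, rw, metric="euclidean")
    raise ValueError(f"distance must be one of {DISTANCES}")


class KNNVarietyClassifier(BaseEstimator, ClassifierMixin):
    """K-nearest-neighbours with chemometric transforms and distances.

    Votes are majority over the k nearest training rows; vote ties are broken
    by the smaller summed neighbour distance, then by the smaller label id.

    Parameters
    ----------
    k : neighbourhood size (>= 1).
    transform : one of {none, mean_center, min_max, log}; statistics are
        learned from the training rows only.
    distance : one of {standardized_euclidean, correlation, mahalanobis}.
    cov_shrinkage : Mahalanobis shrinkage intensity in [0, 1], or None for
        the analytic Ledoit-Wolf choice.
    """

    def __init__(self, k: int = 17, transform: str = "none",
                 distance: str = "standardized_euclidean",
                 cov_shrinkage: float | None = None):
        self.k = k
        self.transform = transform
        self.distance = distance
        self.cov_shrinkage = cov_shrinkage

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.shape[0] == 0:
            raise ValueError("empty training set")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.k > X.shape[0]:
            raise ValueError(f"k={self.k} exceeds training size {X.shape[0]}")
        self.transform_ = SpectrumTransform(self.transform).fit(X)
        self.X_ = self.transform_.transform(X)
        self.classes_ = np.unique(y)
        self.y_ = y.copy()
        return self

    def predict(self, X):
        check_is_fitted(self, "X_")
        Xt = self.transform_.transform(np.asarray(X, dtype=float))
        D = _pairwise(Xt, self.X_, self.distance, self.cov_shrinkage)
        nn = np.argpartition(D, self.k - 1, axis=1)[:, : self.k]
        out = np.empty(Xt.shape[0], dtype=self.y_.dtype)
        for i in range(Xt.shape[0]):
            labels = self.y_[nn[i]]
            dists = D[i, nn[i]]
            cand = np.unique(labels)
            votes = np.array([(labels == c).sum() for c in cand])
            sums = np.array([dists[labels == c].sum() for c in cand])
            # majority vote; ties -> smaller summed distance -> smaller label
            order = np.lexsort((cand, sums, -votes))
            out[i] = cand[order[0]]
        return out


class ELMClassifier(BaseEstimator, ClassifierMixin):
    """Extreme learning machine: random sigmoid hidden layer + least squares.

    Input weights and biases are drawn uniform in [-1, 1] from
    ``random_state``; the output weights are the minimum-norm least-squares
    solution of ``H beta = T`` with one-hot {0, 1} targets. Prediction is the
    argmax over class scores (ties resolve toward the smaller class id).
    """

    def __init__(self, hidden_nodes: int = 150, random_state: int | None = 0):
        self.hidden_nodes = hidden_nodes
        self.random_state = random_state

    def _hidden(self, X: np.ndarray) -> np.ndarray:
        return expit(X @ self.input_weights_ + self.biases_)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if self.hidden_nodes < 1:
            raise ValueError("hidden_nodes must be >= 1")
        if X.shape[0] == 0:
            raise ValueError("empty training set")
        if np.all(X == X[0]):
            import warnings

            warnings.warn("all training rows identical; ELM fit is degenerate")
        rng = np.random.default_rng(self.random_state)
        self.classes_ = np.unique(y)
        # one row of draws per hidden unit, so for a shared seed the first H
        # units of a larger network coincide with a smaller one (nested draws)
        unit_draws = rng.uniform(-1.0, 1.0, size=(self.hidden_nodes, X.shape[1] + 1))
        self.input_weights_ = unit_draws[:, : X.shape[1]].T.copy()
        self.biases_ = unit_draws[:, X.shape[1]].copy()
        H = self._hidden(X)
        T = (y[:, None] == self.classes_[None, :]).astype(float)
        self.output_weights_, *_ = np.linalg.lstsq(H, T, rcond=None)
        return self

    def decision_function(self, X):
        check_is_fitted(self, "output_weights_")
        return self._hidden(np.asarray(X, dtype=float)) @ self.output_weights_

    def predict(self, X):
        scores = self.decision_function(X)
        return self.classes_[np.argmax(scores, axis=1)]


# ---------------------------------------------------------------------------
# thin functional wrappers over the estimators


def knn_predict(train: SpectrumSet, test: SpectrumSet, k: int = 17,
                transform: str = "none",
                distance: str = "standardized_euclidean",
                cov_shrinkage: float | None = None) -> np.ndarray:
    clf = KNNVarietyClassifier(k, transform, distance, cov_shrinkage)
    return clf.fit(train.spectra, train.labels).predict(test.spectra)


def elm_train(train: SpectrumSet, hidden_nodes: int, rng_seed: int = 0) -> ELMClassifier:
    return ELMClassifier(hidden_nodes, rng_seed).fit(train.spectra, train.labels)


def elm_predict(model: ELMClassifier, test: SpectrumSet) -> np.ndarray:
    return model.predict(test.spectra)


def knn_grid_search(
    train: SpectrumSet,
    k_range=range(1, 21),
    transforms=("mean_center", "min_max", "log"),
    distances=DISTANCES,
    n_folds: int = 5,
    rng_seed: int = 0,
    cov_shrinkage: float | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Full factorial sweep of k x transform x distance, CV-averaged.

    Returns the long-form accuracy table and the argmax cell (ties resolve to
    the first row in table order, which is deterministic for a fixed seed).
    """
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=rng_seed)
    folds = list(skf.split(train.spectra, train.labels))
    rows = []
    for transform, distance in itertools.product(transforms, distances):
        accs = {k: [] for k in k_range}
        for tr_idx, va_idx in folds:
            Xtr, ytr = train.spectra[tr_idx], train.labels[tr_idx]
            Xva, yva = train.spectra[va_idx], train.labels[va_idx]
            tf = SpectrumTransform(transform).fit(Xtr)
            Xtr_t, Xva_t = tf.transform(Xtr), tf.transform(Xva)
            D = _pairwise(Xva_t, Xtr_t, distance, cov_shrinkage)
            order = np.argsort(D, axis=1)
            for k in k_range:
                nn_labels = ytr[order[:, :k]]
                pred = np.empty(len(yva), dtype=ytr.dtype)
                for i in range(len(yva)):
                    labels = nn_labels[i]
                    cand, counts = np.unique(labels, return_counts=True)
                    best = counts == counts.max()
                    if best.sum() == 1:
                        pred[i] = cand[np.argmax(counts)]
                    else:
                        dsel = D[i, order[i, :k]]
                        sums = np.array(
                            [dsel[labels == c].sum() for c in cand[best]]
                        )
                        tied = cand[best]
                        pred[i] = tied[np.lexsort((tied, sums))[0]]
                accs[k].append(float(np.mean(pred == yva)))
        for k in k_range:
            rows.append(dict(k=k, transform=transform, distance=distance,
                             accuracy=float(np.mean(accs[k]))))
    table = pd.DataFrame(rows)
    best = table.iloc[int(table["accuracy"].idxmax())].to_dict()
    return table, best
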