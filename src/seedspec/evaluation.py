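"""Splits, stratified 10-fold cross-validation, metrics and report tables.

Accuracy is trace/N of the confusion matrix; Precision, Recall and F1 are
per-class one-vs-rest values macro-averaged (unweighted class mean — with
exactly balanced classes this equals the weighted mean). Cross-validation
reports the fold mean of each metric together with (max - mean) and
(mean - min) deviations, plus the mean per-sample inference time, matching
the usual ``mean +dev/-dev`` presentation of chemometric comparison tables.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split

from .preprocess import PreprocessConfig, SpectralSmoother
from .types import SpectrumSet

__all__ = [
    "FoldPlan",
    "EvalReport",
    "split_4to1",
    "make_folds",
    "confusion_matrix",
    "metrics_from_confusion",
    "cross_entropy",
    "cross_validate",
]


@dataclass(frozen=True)
class FoldPlan:
    """Disjoint fold assignment per sample; folds cover all samples."""

    n_folds: int
    assignments: np.ndarray
    stratified: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        a = np.asarray(self.assignments, dtype=int)
        object.__setattr__(self, "assignments", a)
        if set(np.unique(a)) != set(range(self.n_folds)):
            raise ValueError("assignments must use every fold index 0..n_folds-1")

    def split(self):
        for f in range(self.n_folds):
            test = np.flatnonzero(self.assignments == f)
            train = np.flatnonzero(self.assignments != f)
            yield train, test


def split_4to1(sset: SpectrumSet, rng_seed: int = 0) -> tuple[SpectrumSet, SpectrumSet]:
    """Stratified 4:1 train/test split (e.g. 72/18 of each 90-seed class)."""
    idx = np.arange(sset.n_samples)
    train_idx, test_idx = train_test_split(
        idx, test_size=0.2, stratify=sset.labels, random_state=rng_seed
    )
    return (
        sset.subset(np.sort(train_idx), provenance=sset.provenance + " | train(4:1)"),
        sset.subset(np.sort(test_idx), provenance=sset.provenance + " | test(4:1)"),
    )


def make_folds(sset_or_labels, n_folds: int = 10, rng_seed: int = 0) -> FoldPlan:
    """Stratified fold plan: 2,700 balanced samples -> 10 folds of 270."""
    labels = (
        sset_or_labels.labels
        if isinstance(sset_or_labels, SpectrumSet)
        else np.asarray(sset_or_labels)
    )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=rng_seed)
    assignments = np.empty(labels.shape[0], dtype=int)
    for f, (_, test_idx) in enumerate(skf.split(np.zeros_like(labels)[:, None], labels)):
        assignments[test_idx] = f
    return FoldPlan(n_folds, assignments, stratified=True, rng_seed=rng_seed)


def confusion_matrix(y_true, y_pred, classes=None) -> np.ndarray:
    """C x C count matrix, rows = true class, columns = predicted."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if classes is None:
        classes = np.unique(np.concatenate([y_true, y_pred]))
    classes = np.asarray(classes)
    ti = np.searchsorted(classes, y_true)
    pi = np.searchsorted(classes, y_pred)
    conf = np.zeros((classes.size, classes.size), dtype=int)
    np.add.at(conf, (ti, pi), 1)
    return conf


def metrics_from_confusion(confusion: np.ndarray) -> dict:
    """Accuracy (trace/N) and macro Precision/Recall/F1 from per-class
    one-vs-rest TP/FP/TN/FN counts. Classes with no predicted (or no true)
    samples contribute 0 to the corresponding macro average."""
    conf = np.asarray(confusion, dtype=float)
    if conf.size == 0 or conf.sum() == 0:
        raise ValueError("empty confusion matrix")
    n = conf.sum()
    tp = np.diag(conf)
    fp = conf.sum(axis=0) - tp
    fn = conf.sum(axis=1) - tp
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / denom, 0.0)
    return {
        "accuracy": float(tp.sum() / n),
        "macro_precision": float(precision.mean()),
        "macro_recall": float(recall.mean()),
        "macro_f1": float(f1.mean()),
        "per_class_precision": precision,
        "per_class_recall": recall,
        "per_class_f1": f1,
    }


def cross_entropy(probabilities: np.ndarray, labels: np.ndarray,
                  classes: np.ndarray | None = None) -> float:
    """Mean over samples of the negative log-probability of the true class."""
    p = np.asarray(probabilities, dtype=float)
    labels = np.asarray(labels)
    if classes is None:
        classes = np.unique(labels)
    idx = np.searchsorted(np.asarray(classes), labels)
    return float(-np.log(p[np.arange(len(labels)), idx]).mean())


_METRICS = ("train_accuracy", "accuracy", "macro_precision", "macro_recall", "macro_f1")


@dataclass
class EvalReport:
    """Aggregated cross-validation outcome.

    ``metrics`` maps each metric name to ``{mean, plus_dev, minus_dev,
    per_fold}`` where the deviations are (max - mean) and (mean - min) across
    folds. ``confusion`` sums the per-fold test confusions, so its entries
    total N. ``time_ms`` is the mean per-sample inference time.
    """

    confusion: np.ndarray
    metrics: dict
    time_ms: float
    n_folds: int

    @property
    def accuracy(self) -> float:
        return self.metrics["accuracy"]["mean"]

    def summary_row(self) -> dict:
        row = {}
        for name in _METRICS:
            m = self.metrics[name]
            row[name] = m["mean"]
            row[name + "_plus"] = m["plus_dev"]
            row[name + "_minus"] = m["minus_dev"]
        row["time_ms"] = self.time_ms
        return row

    def to_dict(self) -> dict:
        return {
            "n_folds": self.n_folds,
            "time_ms": self.time_ms,
            "metrics": {
                k: {kk: (list(vv) if isinstance(vv, (list, np.ndarray)) else vv)
                    for kk, vv in v.items()}
                for k, v in self.metrics.items()
            },
            "confusion": self.confusion.tolist(),
        }

    def format_table_row(self, name: str) -> str:
        def cell(metric):
            m = self.metrics[metric]
            return f"{100 * m['mean']:.2f}% +{100 * m['plus_dev']:.2f}%/-{100 * m['minus_dev']:.2f}%"

        return "\t".join(
            [name, cell("train_accuracy"), cell("accuracy"), cell("macro_precision"),
             cell("macro_recall"), cell("macro_f1"), f"{self.time_ms:.2f}ms"]
        )


def _aggregate(per_fold: list[dict], confusion: np.ndarray, time_ms: float,
               n_folds: int) -> EvalReport:
    metrics = {}
    for name in _METRICS:
        vals = np.array([f[name] for f in per_fold])
        metrics[name] = {
            "mean": float(vals.mean()),
            "plus_dev": float(vals.max() - vals.mean()),
            "minus_dev": float(vals.mean() - vals.min()),
            "per_fold": vals.tolist(),
        }
    return EvalReport(confusion, metrics, time_ms, n_folds)


def cross_validate(
    model_factory,
    X,
    y,
    plan: FoldPlan,
    preprocess: PreprocessConfig | None = None,
) -> EvalReport:
    """Stratified k-fold evaluation of ``model_factory()`` estimators.

    The smoothing operators are per-spectrum maps with no cross-sample
    statistics, so applying them inside each fold is leakage-free by
    construction; any statistics an estimator fits (per-band standardization,
    transform parameters, covariances) are learned from the training fold
    only because fitting happens per fold.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if preprocess is not None and preprocess.method != "none":
        sm = SpectralSmoother(preprocess.method, preprocess.window,
                              preprocess.polyorder, preprocess.sigma)
        X = sm.fit_transform(X)
    classes = np.unique(y)
    confusion = np.zeros((classes.size, classes.size), dtype=int)
    per_fold = []
    times = []
    for train_idx, test_idx in plan.split():
        model = model_factory()
        model.fit(X[train_idx], y[train_idx])
        t0 = time.perf_counter()
        pred = model.predict(X[test_idx])
        times.append(1000.0 * (time.perf_counter() - t0) / len(test_idx))
        conf = confusion_matrix(y[test_idx], pred, classes)
        confusion += conf
        fold_metrics = {k: v for k, v in metrics_from_confusion(conf).items()
                        if not k.startswith("per_class")}
        train_pred = model.predict(X[train_idx])
        fold_metrics["train_accuracy"] = float(np.mean(train_pred == y[train_idx]))
        per_fold.append(fold_metrics)
    return _aggregate(per_fold, confusion, float(np.mean(times)), plan.n_folds)
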