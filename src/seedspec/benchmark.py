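"""The standard synthetic model-comparison benchmark.

Runs the five headline classifiers — KNN (k=17, Mahalanobis, log transform),
ELM (150 hidden nodes), CNN1c, CNN2c and CNN2c-SE — on the default
30-variety x 90-seed benchmark under a stratified 4:1 split, replicated over
several seeds, and reports mean test accuracies. This is the package's
standing comparison harness; the expected qualitative outcome on the default
difficulty is the ordering CNN2c-SE >= CNN2c >= CNN1c > ELM > KNN.
"""

from __future__ import annotations

import numpy as np

from .classic import ELMClassifier, KNNVarietyClassifier
from .cnn import SpectralCNNClassifier
from .evaluation import split_4to1
from .synthetic import default_benchmark

__all__ = ["run_model_comparison", "MODEL_ORDER"]

MODEL_ORDER = ("cnn2c_se", "cnn2c", "cnn1c", "elm", "knn")


def _fit_predict(name: str, train, test, seed: int, n_iter: int):
    if name == "knn":
        clf = KNNVarietyClassifier(k=17, transform="log", distance="mahalanobis")
    elif name == "elm":
        clf = ELMClassifier(hidden_nodes=150, random_state=seed)
    else:
        clf = SpectralCNNClassifier(variant=name, n_iter=n_iter, random_state=seed)
    clf.fit(train.spectra, train.labels)
    acc = float(np.mean(clf.predict(test.spectra) == test.labels))
    fit_time = getattr(clf, "fit_time_s_", None)
    return acc, fit_time


def run_model_comparison(
    rng_seed: int = 1,
    n_seeds: int = 5,
    n_iter: int = 2000,
    models: tuple[str, ...] = MODEL_ORDER,
) -> dict:
    """Replicate the five-model comparison over ``n_seeds`` seeds.

    Each replicate re-splits the default benchmark 4:1 with its own seed and
    retrains every model. Returns per-model mean accuracy, per-seed
    accuracies and the per-fit times of the slowest model family.
    """
    data = default_benchmark(rng_seed)
    accs: dict[str, list[float]] = {m: [] for m in models}
    fit_times: dict[str, list[float]] = {m: [] for m in models}
    for rep in range(n_seeds):
        seed = rng_seed + 1000 * (rep + 1)
        train, test = split_4to1(data, rng_seed=seed)
        for name in models:
            acc, ft = _fit_predict(name, train, test, seed, n_iter)
            accs[name].append(acc)
            if ft is not None:
                fit_times[name].append(ft)
    return {
        "mean_accuracy": {m: float(np.mean(accs[m])) for m in models},
        "per_seed_accuracy": {m: accs[m] for m in models},
        "fit_time_s": {m: fit_times[m] for m in models if fit_times[m]},
        "n_seeds": n_seeds,
        "n_iter": n_iter,
    }
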