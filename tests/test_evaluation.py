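"""Split bookkeeping, fold plans, metric formulas and CV aggregation."""

import numpy as np
import pytest
from sklearn.dummy import DummyClassifier
from sklearn.metrics import precision_score, recall_score, f1_score

from seedspec import (
    ELMClassifier,
    FoldPlan,
    NoiseModel,
    confusion_matrix,
    cross_entropy,
    cross_validate,
    gen_spectrum_set,
    make_folds,
    make_varieties,
    metrics_from_confusion,
    split_4to1,
)
from seedspec.preprocess import PreprocessConfig


@pytest.fixture(scope="module")
def benchmark_set():
    return gen_spectrum_set(make_varieties(30, 7), 90, NoiseModel(seed=8))


class TestSplit:
    def test_exact_4to1_bookkeeping(self, benchmark_set):
        train, test = split_4to1(benchmark_set, rng_seed=0)
        assert benchmark_set.n_samples == 2700
        assert train.n_samples == 2160 and test.n_samples == 540
        for c in range(1, 31):
            assert (train.labels == c).sum() == 72
            assert (test.labels == c).sum() == 18

    def test_partition_property(self, benchmark_set):
        train, test = split_4to1(benchmark_set, rng_seed=1)
        combined = np.vstack([train.spectra, test.spectra])
        # every input row appears exactly once across the two halves
        assert combined.shape[0] == benchmark_set.n_samples
        order = np.lexsort(combined.T)
        base = np.lexsort(benchmark_set.spectra.T)
        assert np.allclose(combined[order], benchmark_set.spectra[base])

    def test_reproducible(self, benchmark_set):
        a_train, _ = split_4to1(benchmark_set, rng_seed=3)
        b_train, _ = split_4to1(benchmark_set, rng_seed=3)
        assert np.array_equal(a_train.spectra, b_train.spectra)


class TestFolds:
    def test_fold_sizes_and_stratification(self, benchmark_set):
        plan = make_folds(benchmark_set, 10, rng_seed=2)
        sizes = np.bincount(plan.assignments)
        assert np.all(sizes == 270)
        for f in range(10):
            labels = benchmark_set.labels[plan.assignments == f]
            assert np.all(np.bincount(labels)[1:] == 9)

    def test_deterministic(self, benchmark_set):
        a = make_folds(benchmark_set, 10, rng_seed=4)
        b = make_folds(benchmark_set, 10, rng_seed=4)
        assert np.array_equal(a.assignments, b.assignments)

    def test_invalid_assignments_rejected(self):
        with pytest.raises(ValueError):
            FoldPlan(3, np.array([0, 0, 1, 1]))  # fold 2 missing


class TestMetrics:
    def test_identity_confusion_all_ones(self):
        m = metrics_from_confusion(np.eye(5) * 7)
        assert m["accuracy"] == 1.0
        assert m["macro_precision"] == m["macro_recall"] == m["macro_f1"] == 1.0

    def test_hand_evaluated_two_class_matrix(self):
        m = metrics_from_confusion(np.array([[8, 2], [3, 7]]))
        assert m["accuracy"] == pytest.approx(0.75)
        assert m["per_class_precision"][0] == pytest.approx(8 / 11)
        assert m["per_class_recall"][0] == pytest.approx(0.8)

    def test_degenerate_single_class_predictions(self):
        conf = np.zeros((30, 30))
        conf[:, 0] = 9  # balanced truth, everything predicted as class 1
        m = metrics_from_confusion(conf)
        assert m["accuracy"] == pytest.approx(1 / 30)

    def test_matches_per_sample_counting_oracle(self, rng):
        y_true = rng.integers(0, 30, size=1000)
        y_pred = rng.integers(0, 30, size=1000)
        conf = confusion_matrix(y_true, y_pred, classes=np.arange(30))
        m = metrics_from_confusion(conf)
        assert m["accuracy"] == pytest.approx(np.mean(y_true == y_pred))
        labels = np.arange(30)
        assert m["macro_precision"] == pytest.approx(
            precision_score(y_true, y_pred, labels=labels, average="macro", zero_division=0))
        assert m["macro_recall"] == pytest.approx(
            recall_score(y_true, y_pred, labels=labels, average="macro", zero_division=0))
        assert m["macro_f1"] == pytest.approx(
            f1_score(y_true, y_pred, labels=labels, average="macro", zero_division=0))

    def test_micro_recall_equals_accuracy(self, rng):
        conf = rng.integers(0, 20, size=(8, 8))
        conf[0, 0] += 1  # non-empty
        m = metrics_from_confusion(conf)
        tp = np.diag(conf).sum()
        assert m["accuracy"] == pytest.approx(tp / conf.sum())

    def test_empty_confusion_rejected(self):
        with pytest.raises(ValueError):
            metrics_from_confusion(np.zeros((3, 3)))


class TestCrossEntropy:
    def test_perfect_one_hot_is_zero(self):
        p = np.eye(4)[[0, 1, 2, 3]]
        p = np.clip(p, 1e-15, 1.0)
        assert cross_entropy(p, np.arange(4)) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_30_classes_is_log30(self):
        p = np.full((12, 30), 1 / 30)
        assert cross_entropy(p, np.arange(12) % 30, classes=np.arange(30)) == \
            pytest.approx(np.log(30))

    def test_matches_explicit_per_sample_sum(self, rng):
        p = rng.dirichlet(np.ones(5), size=20)
        y = rng.integers(0, 5, size=20)
        expected = -sum(np.log(p[i, y[i]]) for i in range(20)) / 20
        assert cross_entropy(p, y, classes=np.arange(5)) == pytest.approx(expected)


class TestCrossValidate:
    def test_constant_classifier_zero_deviation(self, small_set):
        plan = make_folds(small_set.labels, 4, rng_seed=0)
        report = cross_validate(
            lambda: DummyClassifier(strategy="constant", constant=1),
            small_set.spectra, small_set.labels, plan,
        )
        assert report.accuracy == pytest.approx(1 / 5)
        assert report.metrics["accuracy"]["plus_dev"] == pytest.approx(0.0)
        assert report.metrics["accuracy"]["minus_dev"] == pytest.approx(0.0)
        assert report.confusion.sum() == small_set.n_samples

    def test_invariant_to_sample_order_given_plan(self, small_set, rng):
        plan = make_folds(small_set.labels, 3, rng_seed=1)
        rep_a = cross_validate(lambda: ELMClassifier(30, 0),
                               small_set.spectra, small_set.labels, plan)
        perm = rng.permutation(small_set.n_samples)
        plan_p = FoldPlan(3, plan.assignments[perm], rng_seed=1)
        rep_b = cross_validate(lambda: ELMClassifier(30, 0),
                               small_set.spectra[perm], small_set.labels[perm], plan_p)
        assert rep_a.accuracy == pytest.approx(rep_b.accuracy)
        assert np.array_equal(rep_a.confusion, rep_b.confusion)

    def test_preprocess_applied_inside_cv(self, small_set):
        plan = make_folds(small_set.labels, 3, rng_seed=2)
        report = cross_validate(lambda: ELMClassifier(50, 0),
                                small_set.spectra, small_set.labels, plan,
                                preprocess=PreprocessConfig("sg", 11, 3))
        assert 0.0 <= report.accuracy <= 1.0
        row = report.format_table_row("SG")
        assert row.startswith("SG\t") and row.endswith("ms")

    def test_shuffled_labels_give_chance_accuracy(self, benchmark_set, rng):
        # permutation null: destroy the label-spectrum link; a leakage-free
        # harness must fall to 1/30 within binomial sampling error
        y_null = rng.permutation(benchmark_set.labels)
        plan = make_folds(y_null, 10, rng_seed=3)
        report = cross_validate(lambda: ELMClassifier(60, 0),
                                benchmark_set.spectra, y_null, plan)
        p = 1 / 30
        sigma = np.sqrt(p * (1 - p) / benchmark_set.n_samples)
        assert abs(report.accuracy - p) < 3 * sigma
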