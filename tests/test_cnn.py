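"""SE block, forward contracts, gradients and training behaviour."""

import numpy as np
import pytest

from seedspec import (
    NoiseModel,
    SpectralCNNClassifier,
    ablate,
    gen_spectrum_set,
    make_folds,
    make_varieties,
    se_block,
    softmax,
)
from seedspec.cnn import ModelSpec, _sigmoid


class TestSeBlock:
    def _weights(self, rng, c=4, r=2):
        return (rng.normal(size=(c, c // r)), rng.normal(size=c // r),
                rng.normal(size=(c // r, c)), rng.normal(size=c))

    def test_constant_channel_squeeze(self, rng):
        W1, b1, W2, b2 = self._weights(rng)
        x = np.tile(np.array([1.0, -2.0, 0.5, 3.0])[:, None], (1, 8))
        _, gates = se_block(x, W1, b1, W2, b2)
        # the squeeze of a constant channel is exactly its value, so gates
        # equal the excitation of the channel-value vector
        s = np.array([1.0, -2.0, 0.5, 3.0])
        h = np.maximum(s @ W1 + b1, 0)
        assert np.allclose(gates, _sigmoid(h @ W2 + b2))

    def test_identity_gate_limit(self, rng):
        W1, b1, W2, b2 = self._weights(rng)
        x = rng.normal(size=(4, 8))
        out, gates = se_block(x, W1 * 0, b1, W2 * 0, b2 + 50.0)  # pre-sigmoid -> +50
        assert np.allclose(gates, 1.0, atol=1e-20)
        assert np.allclose(out, x)

    def test_matches_step_by_step_matrix_oracle(self, rng):
        W1, b1, W2, b2 = self._weights(rng)
        x = rng.normal(size=(4, 8))
        out, gates = se_block(x, W1, b1, W2, b2)
        # hand-rolled forward: explicit loops, no vectorized reuse
        s = np.array([x[c].sum() / 8 for c in range(4)])
        h = np.array([max(0.0, sum(s[i] * W1[i, j] for i in range(4)) + b1[j])
                      for j in range(2)])
        z = np.array([sum(h[j] * W2[j, c] for j in range(2)) + b2[c] for c in range(4)])
        g = 1.0 / (1.0 + np.exp(-z))
        expected = np.array([[x[c, l] * g[c] for l in range(8)] for c in range(4)])
        assert np.allclose(gates, g)
        assert np.allclose(out, expected)

    def test_gates_bound_output(self, rng):
        W1, b1, W2, b2 = self._weights(rng)
        x = rng.normal(size=(4, 8))
        out, gates = se_block(x, W1, b1, W2, b2)
        assert np.all((gates > 0) & (gates < 1))
        assert np.all(np.abs(out).max(axis=1) <= np.abs(x).max(axis=1))


class TestForward:
    @pytest.fixture(scope="class")
    def fitted(self):
        sset = gen_spectrum_set(make_varieties(30, 2), 3, NoiseModel(seed=3))
        clf = SpectralCNNClassifier(variant="cnn2c_se", n_iter=5, random_state=0)
        return clf.fit(sset.spectra, sset.labels), sset

    def test_output_shape_contract(self, fitted):
        clf, sset = fitted
        assert clf.decision_function(sset.spectra[:7]).shape == (7, 30)

    @pytest.mark.parametrize("variant", ["cnn1c", "cnn2c", "cnn3c", "cnn2c_se"])
    def test_all_variants_forward(self, variant):
        sset = gen_spectrum_set(make_varieties(4, 2), 3, NoiseModel(seed=3))
        clf = SpectralCNNClassifier(variant=variant, n_iter=3, random_state=0)
        clf.fit(sset.spectra, sset.labels)
        probs = clf.predict_proba(sset.spectra[:5])
        assert probs.shape == (5, 4)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_zero_weights_give_uniform_probabilities(self, fitted):
        clf, sset = fitted
        zeroed = {k: np.zeros_like(v) for k, v in clf.params_.items()}
        saved = clf.params_
        clf.params_ = zeroed
        try:
            probs = clf.predict_proba(sset.spectra[:4])
        finally:
            clf.params_ = saved
        assert np.allclose(probs, 1.0 / 30)

    def test_wrong_band_count_rejected(self, fitted):
        clf, _ = fitted
        with pytest.raises(ValueError):
            clf.predict(np.zeros((2, 100)))

    def test_uniform_prediction_cross_entropy_is_log30(self):
        # closed form of the multiclass loss at maximal uncertainty
        probs = np.full((10, 30), 1.0 / 30)
        loss = -np.log(probs[np.arange(10), 0]).mean()
        assert loss == pytest.approx(np.log(30), abs=1e-12)


class TestGradients:
    @pytest.mark.parametrize("variant", ["cnn1c", "cnn2c_se"])
    def test_backprop_matches_finite_differences(self, variant, rng):
        # float64 end-to-end so central differences are trustworthy
        n_bands, n_classes, n = 16, 3, 6
        X = rng.normal(size=(n, n_bands))
        y = rng.integers(0, n_classes, size=n)
        clf = SpectralCNNClassifier(variant=variant, conv_channels=(3, 4)[: 1 if variant == "cnn1c" else 2],
                                    fc_hidden=() if variant == "cnn1c" else (5,),
                                    se_ratio=2, n_iter=1, standardize=False, random_state=0)
        clf.fit(X, y)
        spec = ModelSpec(variant, tuple(clf.conv_channels), tuple(clf.fc_hidden or ()),
                         2, n_classes, n_bands)
        params = {k: rng.normal(size=v.shape) for k, v in clf.params_.items()}

        def loss_of(p):
            logits, _ = clf._forward(X, p, spec)
            probs = softmax(logits)
            return -np.log(probs[np.arange(n), y]).mean()

        logits, cache = clf._forward(X, params, spec)
        probs = softmax(logits)
        dlogits = probs.copy()
        dlogits[np.arange(n), y] -= 1
        dlogits /= n
        grads = clf._backward(dlogits, params, spec, cache)

        h = 1e-6
        for key in params:
            flat = params[key].reshape(-1)
            for idx in rng.choice(flat.size, size=min(5, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + h
                up = loss_of(params)
                flat[idx] = orig - h
                down = loss_of(params)
                flat[idx] = orig
                fd = (up - down) / (2 * h)
                assert grads[key].reshape(-1)[idx] == pytest.approx(fd, rel=1e-4, abs=1e-8), key


class TestTraining:
    def test_capacity_sanity_two_classes(self):
        sset = gen_spectrum_set(make_varieties(2, 6), 20, NoiseModel.silent(1))
        clf = SpectralCNNClassifier(variant="cnn1c", n_iter=500, random_state=0)
        clf.fit(sset.spectra, sset.labels)
        assert clf.score(sset.spectra, sset.labels) == 1.0

    def test_loss_trace_reproducible(self, small_set):
        kw = dict(variant="cnn2c_se", n_iter=25, random_state=5)
        a = SpectralCNNClassifier(**kw).fit(small_set.spectra, small_set.labels)
        b = SpectralCNNClassifier(**kw).fit(small_set.spectra, small_set.labels)
        assert np.array_equal(a.loss_trace_, b.loss_trace_)
        assert len(a.loss_trace_) == 25
        assert np.all(np.isfinite(a.loss_trace_))

    def test_dropout_l1_early_stop_paths(self, small_set):
        clf = SpectralCNNClassifier(
            variant="cnn2c_se", n_iter=150, dropout_p=0.2, l1_lambda=1e-5,
            early_stop_patience=2, eval_interval=15, validation_fraction=0.25,
            random_state=3,
        ).fit(small_set.spectra, small_set.labels)
        assert clf.n_steps_ <= 150
        assert np.all(np.isfinite(clf.loss_trace_))

    def test_conv_length_preserved_all_depths(self):
        # (3,1,1) convolutions must keep 320 bands until flattening
        sset = gen_spectrum_set(make_varieties(3, 8), 4, NoiseModel(seed=8))
        for variant in ("cnn1c", "cnn2c", "cnn3c"):
            clf = SpectralCNNClassifier(variant=variant, n_iter=2, random_state=0)
            clf.fit(sset.spectra, sset.labels)
            X32 = clf._scale(sset.spectra[:2]).astype(np.float32)
            _, cache = clf._forward(X32, clf.params_, clf.model_spec_)
            c_last = clf.model_spec_.conv_channels[-1]
            assert cache["pre_flat_shape"] == (2, 320, c_last)


def test_ablate_table_schema(small_set):
    plan = make_folds(small_set.labels, n_folds=2, rng_seed=0)
    table = ablate(
        [{"variant": "cnn2c_se", "se_ratio": 8}, {"variant": "cnn2c_se", "se_ratio": 16}],
        small_set.spectra, small_set.labels, plan,
        base_params={"n_iter": 20, "random_state": 0},
    )
    assert len(table) == 2
    for col in ("config", "train_accuracy", "accuracy", "macro_precision",
                "macro_recall", "macro_f1", "time_ms"):
        assert col in table.columns
    assert (table["accuracy_plus"] >= 0).all() and (table["accuracy_minus"] >= 0).all()
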