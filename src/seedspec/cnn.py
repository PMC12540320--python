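"""1-D convolutional networks for full-band spectra, with SE channel attention.

The model family:

* ``cnn1c`` — one conv layer (kernel 3, stride 1, padding 1) + one fully
  connected output layer;
* ``cnn2c`` — two conv layers + two fully connected layers;
* ``cnn3c`` — three conv layers + three fully connected layers;
* ``cnn2c_se`` — ``cnn2c`` with one squeeze-and-excitation (SE) block after
  the second convolution's ReLU.

The SE block computes a per-channel scalar by global average pooling
(squeeze), passes the pooled vector through a two-layer bottleneck
``FC(C -> C/r) + ReLU + FC(C/r -> C) + sigmoid`` (excitation), and rescales
each channel by its gate. All convolutions use (kernel, stride, padding) =
(3, 1, 1), so the 320-band length is preserved up to flattening; there is no
pooling by default.

Training minimizes the multiclass cross-entropy with the Adam optimizer
(learning rate 0.01, batch size 64, 10,000 mini-batch update steps by
default). Optional extras: dropout after the first hidden FC layer, L1
weight regularization, and early stopping on a validation set. Everything is
plain NumPy with hand-written backpropagation; the networks are small enough
that a single CPU core trains them in tens of seconds at reduced iteration
counts.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "ConvSpec",
    "SeBlockSpec",
    "TrainSpec",
    "ModelSpec",
    "se_block",
    "softmax",
    "SpectralCNNClassifier",
    "ablate",
]

VARIANTS = ("cnn1c", "cnn2c", "cnn3c", "cnn2c_se")


@dataclass(frozen=True)
class ConvSpec:
    out_channels: int
    kernel_size: int = 3
    stride: int = 1
    padding: int = 1


@dataclass(frozen=True)
class SeBlockSpec:
    channels: int
    ratio: int = 16

    @property
    def bottleneck(self) -> int:
        return max(1, self.channels // self.ratio)


@dataclass(frozen=True)
class TrainSpec:
    learning_rate: float = 0.01  # initial rate; warmed up then cosine-decayed
    batch_size: int = 64
    iterations: int = 10_000
    warmup_steps: int = 200
    lr_decay: str = "cosine"  # "cosine" or "none"
    l1_lambda: float = 0.0
    dropout_p: float = 0.0
    early_stop_patience: int | None = None
    eval_interval: int = 100
    rng_seed: int = 0


@dataclass(frozen=True)
class ModelSpec:
    variant: str = "cnn2c_se"
    conv_channels: tuple[int, ...] = ()
    fc_hidden: tuple[int, ...] = ()
    se_ratio: int = 16
    n_classes: int = 30
    n_bands: int = 320

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if not self.conv_channels:
            defaults = {"cnn1c": (16,), "cnn2c": (16, 32),
                        "cnn2c_se": (16, 32), "cnn3c": (16, 32, 64)}
            object.__setattr__(self, "conv_channels", defaults[self.variant])
        if not self.fc_hidden:
            defaults = {"cnn1c": (), "cnn2c": (64,),
                        "cnn2c_se": (64,), "cnn3c": (64, 32)}
            object.__setattr__(self, "fc_hidden", defaults[self.variant])

    @property
    def has_se(self) -> bool:
        return self.variant == "cnn2c_se"


# ---------------------------------------------------------------------------
# layer primitives (float32 throughout)


try:  # fused gather/scatter for the (3,1,1) im2col; zero padding at the edges
    from numba import njit as _njit

    @_njit(cache=True)
    def _im2col3(x):  # pragma: no cover - exercised via _conv1d_forward
        N, L, C = x.shape
        cols = np.zeros((N * L, C * 3), dtype=x.dtype)
        for n in range(N):
            for l in range(L):
                row = n * L + l
                for c in range(C):
                    base = c * 3
                    if l > 0:
                        cols[row, base] = x[n, l - 1, c]
                    cols[row, base + 1] = x[n, l, c]
                    if l < L - 1:
                        cols[row, base + 2] = x[n, l + 1, c]
        return cols

    @_njit(cache=True)
    def _col2im3(dcols, N, L, C):  # pragma: no cover
        dx = np.zeros((N, L, C), dtype=dcols.dtype)
        for n in range(N):
            for l in range(L):
                row = n * L + l
                for c in range(C):
                    base = c * 3
                    if l > 0:
                        dx[n, l - 1, c] += dcols[row, base]
                    dx[n, l, c] += dcols[row, base + 1]
                    if l < L - 1:
                        dx[n, l + 1, c] += dcols[row, base + 2]
        return dx

    _HAVE_NUMBA_CONV = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA_CONV = False


def _conv1d_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    """(3,1,1) convolution, channels-last, zero padding.

    x: (N, L, C); W: (C*3, O); b: (O,). The im2col row for position l
    concatenates the window samples per input channel (channel-major,
    tap-minor), matching the (C*3, O) weight layout.
    """
    N, L, C = x.shape
    if _HAVE_NUMBA_CONV:
        cols = _im2col3(np.ascontiguousarray(x))
    else:
        xp = np.zeros((N, L + 2, C), dtype=x.dtype)
        xp[:, 1:-1, :] = x
        cols = sliding_window_view(xp, 3, axis=1)      # (N, L, C, 3)
        cols = np.ascontiguousarray(cols).reshape(N * L, C * 3)
    y = (cols @ W + b).reshape(N, L, -1)
    return y, cols


def _conv1d_backward(dy: np.ndarray, cols: np.ndarray, W: np.ndarray, x_shape):
    N, L, C = x_shape
    dy_mat = dy.reshape(N * L, -1)
    dW = cols.T @ dy_mat
    db = dy_mat.sum(axis=0)
    dcols = np.ascontiguousarray(dy_mat @ W.T)
    if _HAVE_NUMBA_CONV:
        dx = _col2im3(dcols, N, L, C)
    else:
        d4 = dcols.reshape(N, L, C, 3)
        dxp = np.zeros((N, L + 2, C), dtype=dy.dtype)
        for k in range(3):
            dxp[:, k : k + L, :] += d4[:, :, :, k]
        dx = dxp[:, 1 : L + 1, :]
    return dx, dW, db


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def se_block(x: np.ndarray, W1: np.ndarray, b1: np.ndarray,
             W2: np.ndarray, b2: np.ndarray) -> np.ndarray:
    """Squeeze-and-excitation forward pass on a (C, L) or (N, C, L) map.

    Squeeze: global average pool per channel. Excitation: FC -> ReLU -> FC ->
    sigmoid. The resulting gate in (0, 1) rescales its channel.
    """
    single = x.ndim == 2
    if single:
        x = x[None]
    s = x.mean(axis=2)
    h = np.maximum(s @ W1 + b1, 0.0)
    g = _sigmoid(h @ W2 + b2)
    y = x * g[:, :, None]
    return (y[0], g[0]) if single else (y, g)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _adam_update_numpy(p, g, m, v, b1, b2, alpha, eps_hat):
    m *= b1
    m += (1 - b1) * g
    m[np.abs(m) < 1e-30] = 0.0  # flush denormals (see fused kernel note)
    v *= b2
    g = np.square(g, out=g)  # grads are consumed; reuse the buffer
    g *= 1 - b2
    v += g
    v[v < 1e-30] = 0.0
    denom = np.sqrt(v, out=g)
    denom += eps_hat
    np.divide(m, denom, out=denom)
    denom *= alpha
    p -= denom


try:  # fused single-pass kernel; the dict-of-arrays update is bandwidth-bound
    from numba import njit

    @njit(cache=True, fastmath=False)
    def _adam_update_fused(p, g, m, v, b1, b2, alpha, eps_hat):  # pragma: no cover
        # moments are flushed to zero below 1e-30: with vanishing gradients
        # they otherwise decay geometrically into denormal range, where every
        # multiply stalls the pipeline for ~100 cycles
        for i in range(p.size):
            mi = b1 * m[i] + (1.0 - b1) * g[i]
            vi = b2 * v[i] + (1.0 - b2) * g[i] * g[i]
            if -1e-30 < mi < 1e-30:
                mi = 0.0
            if vi < 1e-30:
                vi = 0.0
            m[i] = mi
            v[i] = vi
            p[i] -= alpha * mi / (np.sqrt(vi) + eps_hat)

    def _adam_update(p, g, m, v, b1, b2, alpha, eps_hat):
        _adam_update_fused(p.ravel(), np.ascontiguousarray(g).ravel(),
                           m.ravel(), v.ravel(),
                           np.float32(b1), np.float32(b2),
                           np.float32(alpha), np.float32(eps_hat))
except ImportError:  # pragma: no cover
    _adam_update = _adam_update_numpy


class _Adam:
    def __init__(self, params: dict, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        # bias corrections folded into the step size and epsilon
        alpha = self.lr * np.sqrt(bc2) / bc1
        eps_hat = self.eps * np.sqrt(bc2)
        for k, g in grads.items():
            _adam_update(params[k], g.astype(np.float32, copy=False),
                         self.m[k], self.v[k], self.b1, self.b2, alpha, eps_hat)


# ---------------------------------------------------------------------------


class SpectralCNNClassifier(BaseEstimator, ClassifierMixin):
    """Scikit-learn style classifier wrapping the 1-D CNN family.

    Parameters
    ----------
    variant : {"cnn1c", "cnn2c", "cnn3c", "cnn2c_se"}
    se_ratio : SE bottleneck reduction ratio r (cnn2c_se only).
    learning_rate, batch_size, n_iter : initial Adam step size, mini-batch
        size and number of parameter-update steps.
    warmup_steps, lr_decay : the learning rate ramps linearly to its initial
        value over ``warmup_steps`` updates, then follows a cosine decay
        ("none" disables). Together with the zero-initialized output layer
        this keeps the large first Adam steps at rate 0.01 from blowing up
        the loss and killing ReLU units.
    l1_lambda, dropout_p : optional regularization (0 disables).
    early_stop_patience : stop after this many evaluations without validation
        improvement (requires ``validation_fraction`` > 0 or an explicit
        validation set passed to :meth:`fit`); None disables.
    standardize : per-band z-scoring fitted on the training rows. On by
        default — raw reflectance scales make learning-rate 0.01 unstable.
    random_state : seeds weight init and batch sampling; fits are
        deterministic given it.

    Attributes
    ----------
    params_ : dict of weight arrays.
    loss_trace_ : per-step training-batch cross-entropy.
    classes_ : sorted class labels.
    """

    def __init__(self, variant: str = "cnn2c_se", se_ratio: int = 16,
                 conv_channels: tuple | None = None, fc_hidden: tuple | None = None,
                 learning_rate: float = 0.01, batch_size: int = 64,
                 n_iter: int = 10_000, warmup_steps: int = 200,
                 lr_decay: str = "cosine", l1_lambda: float = 0.0,
                 dropout_p: float = 0.0, early_stop_patience: int | None = None,
                 eval_interval: int = 100, validation_fraction: float = 0.0,
                 standardize: bool = True, random_state: int | None = 0):
        self.variant = variant
        self.se_ratio = se_ratio
        self.conv_channels = conv_channels
        self.fc_hidden = fc_hidden
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.n_iter = n_iter
        self.warmup_steps = warmup_steps
        self.lr_decay = lr_decay
        self.l1_lambda = l1_lambda
        self.dropout_p = dropout_p
        self.early_stop_patience = early_stop_patience
        self.eval_interval = eval_interval
        self.validation_fraction = validation_fraction
        self.standardize = standardize
        self.random_state = random_state

    # -- model assembly ----------------------------------------------------

    def _spec(self, n_classes: int, n_bands: int) -> ModelSpec:
        return ModelSpec(
            variant=self.variant,
            conv_channels=tuple(self.conv_channels or ()),
            fc_hidden=tuple(self.fc_hidden or ()),
            se_ratio=self.se_ratio,
            n_classes=n_classes,
            n_bands=n_bands,
        )

    def _init_params(self, spec: ModelSpec, rng: np.random.Generator) -> dict:
        params: dict[str, np.ndarray] = {}
        c_in = 1
        for i, c_out in enumerate(spec.conv_channels):
            fan_in = c_in * 3
            params[f"convW{i}"] = rng.normal(
                0, np.sqrt(2.0 / fan_in), size=(fan_in, c_out)
            ).astype(np.float32)
            params[f"convb{i}"] = np.zeros(c_out, dtype=np.float32)
            c_in = c_out
        if spec.has_se:
            se = SeBlockSpec(c_in, spec.se_ratio)
            params["seW1"] = rng.normal(
                0, np.sqrt(2.0 / se.channels), size=(se.channels, se.bottleneck)
            ).astype(np.float32)
            params["seb1"] = np.zeros(se.bottleneck, dtype=np.float32)
            params["seW2"] = rng.normal(
                0, np.sqrt(1.0 / se.bottleneck), size=(se.bottleneck, se.channels)
            ).astype(np.float32)
            params["seb2"] = np.zeros(se.channels, dtype=np.float32)
        widths = [c_in * spec.n_bands, *spec.fc_hidden, spec.n_classes]
        for i in range(len(widths) - 1):
            params[f"fcW{i}"] = rng.normal(
                0, np.sqrt(2.0 / widths[i]), size=(widths[i], widths[i + 1])
            ).astype(np.float32)
            params[f"fcb{i}"] = np.zeros(widths[i + 1], dtype=np.float32)
        # zero output layer: initial logits are exactly uniform, which keeps
        # the first optimizer steps from blowing up the loss at lr 0.01
        params[f"fcW{len(widths) - 2}"][:] = 0.0
        return params

    # -- forward / backward ------------------------------------------------

    def _forward(self, X: np.ndarray, params: dict, spec: ModelSpec,
                 train: bool = False, rng: np.random.Generator | None = None):
        cache: dict = {"x_shapes": [], "cols": [], "relu": []}
        dt = params[f"fcb{len(spec.fc_hidden)}"].dtype  # follow parameter dtype
        x = X[:, :, None].astype(dt)  # channels-last: (N, L, C)
        for i in range(len(spec.conv_channels)):
            cache["x_shapes"].append(x.shape)
            y, cols = _conv1d_forward(x, params[f"convW{i}"], params[f"convb{i}"])
            cache["cols"].append(cols)
            x = np.maximum(y, 0.0)
            cache["relu"].append(x > 0)
        if spec.has_se:
            s = x.mean(axis=1)
            h = np.maximum(s @ params["seW1"] + params["seb1"], 0.0)
            g = _sigmoid(h @ params["seW2"] + params["seb2"])
            cache["se"] = (x.copy(), s, h, g)
            x = x * g[:, None, :]
        N = x.shape[0]
        cache["pre_flat_shape"] = x.shape
        a = x.reshape(N, -1)
        n_fc = len(spec.fc_hidden) + 1
        cache["fc_in"] = []
        cache["drop_mask"] = None
        for i in range(n_fc):
            cache["fc_in"].append(a)
            z = a @ params[f"fcW{i}"] + params[f"fcb{i}"]
            if i < n_fc - 1:
                a = np.maximum(z, 0.0)
                if i == 0 and train and self.dropout_p > 0:
                    mask = (rng.random(a.shape) >= self.dropout_p).astype(dt)
                    a = a * mask / (1.0 - self.dropout_p)
                    cache["drop_mask"] = mask
            else:
                a = z
        return a, cache

    def _backward(self, dlogits: np.ndarray, params: dict, spec: ModelSpec,
                  cache: dict) -> dict:
        grads: dict[str, np.ndarray] = {}
        n_fc = len(spec.fc_hidden) + 1
        da = dlogits
        for i in range(n_fc - 1, -1, -1):
            a_in = cache["fc_in"][i]
            grads[f"fcW{i}"] = a_in.T @ da
            grads[f"fcb{i}"] = da.sum(axis=0)
            da = da @ params[f"fcW{i}"].T
            if i > 0:
                if i - 1 == 0 and cache["drop_mask"] is not None:
                    da = da * cache["drop_mask"] / (1.0 - self.dropout_p)
                da = da * (cache["fc_in"][i] > 0)
        dx = da.reshape(cache["pre_flat_shape"])
        if spec.has_se:
            x_in, s, h, g = cache["se"]
            L = x_in.shape[1]
            dg = (x_in * dx).sum(axis=1)
            dx = dx * g[:, None, :]
            dz2 = dg * g * (1.0 - g)
            grads["seW2"] = h.T @ dz2
            grads["seb2"] = dz2.sum(axis=0)
            dh = dz2 @ params["seW2"].T
            dz1 = dh * (h > 0)
            grads["seW1"] = s.T @ dz1
            grads["seb1"] = dz1.sum(axis=0)
            ds = dz1 @ params["seW1"].T
            dx = dx + ds[:, None, :] / L
        for i in range(len(spec.conv_channels) - 1, -1, -1):
            dx = dx * cache["relu"][i]
            dx, dW, db = _conv1d_backward(
                dx, cache["cols"][i], params[f"convW{i}"], cache["x_shapes"][i]
            )
            grads[f"convW{i}"] = dW
            grads[f"convb{i}"] = db
        return grads

    # -- public API --------------------------------------------------------

    def fit(self, X, y, X_val=None, y_val=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.shape[0] == 0:
            raise ValueError("empty training set")
        self.classes_ = np.unique(y)
        rng = np.random.default_rng(self.random_state)

        if X_val is None and self.validation_fraction > 0:
            from sklearn.model_selection import train_test_split

            X, X_val, y, y_val = train_test_split(
                X, y, test_size=self.validation_fraction, stratify=y,
                random_state=int(rng.integers(2**31 - 1)),
            )

        if self.standardize:
            self.mean_ = X.mean(axis=0)
            std = X.std(axis=0)
            std[std == 0] = 1.0
            self.std_ = std
        Xs = self._scale(X).astype(np.float32)
        y_idx = np.searchsorted(self.classes_, y)

        spec = self._spec(len(self.classes_), X.shape[1])
        self.model_spec_ = spec
        params = self._init_params(spec, rng)
        opt = _Adam(params, self.learning_rate)

        n = Xs.shape[0]
        bs = min(self.batch_size, n)
        order = rng.permutation(n)
        cursor = 0
        trace: list[float] = []
        best_val = np.inf
        best_params = None
        stale = 0
        t0 = time.perf_counter()
        warmup = max(0, int(self.warmup_steps))
        for step in range(self.n_iter):
            # schedule: linear warmup to the initial rate, then cosine decay
            lr_t = self.learning_rate
            if warmup and step < warmup:
                lr_t *= (step + 1) / warmup
            if self.lr_decay == "cosine":
                lr_t *= 0.5 * (1.0 + np.cos(np.pi * step / max(1, self.n_iter)))
            opt.lr = lr_t
            if cursor + bs > n:
                order = rng.permutation(n)
                cursor = 0
            idx = order[cursor : cursor + bs]
            cursor += bs
            xb, yb = Xs[idx], y_idx[idx]
            logits, cache = self._forward(xb, params, spec, train=True, rng=rng)
            probs = softmax(logits)
            loss = float(-np.log(probs[np.arange(len(yb)), yb] + 1e-12).mean())
            if not np.isfinite(loss):
                raise FloatingPointError(f"training diverged at step {step}: loss={loss}")
            if self.l1_lambda > 0:
                loss += self.l1_lambda * sum(
                    float(np.abs(v).sum()) for k, v in params.items() if "W" in k
                )
            trace.append(loss)
            dlogits = probs.copy()
            dlogits[np.arange(len(yb)), yb] -= 1.0
            dlogits /= len(yb)
            grads = self._backward(dlogits.astype(np.float32), params, spec, cache)
            if self.l1_lambda > 0:
                for k in grads:
                    if "W" in k:
                        grads[k] = grads[k] + self.l1_lambda * np.sign(params[k])
            opt.step(params, grads)

            if (self.early_stop_patience is not None and X_val is not None
                    and (step + 1) % self.eval_interval == 0):
                val_loss = self._loss_on(X_val, y_val, params, spec)
                if val_loss < best_val - 1e-6:
                    best_val = val_loss
                    best_params = {k: v.copy() for k, v in params.items()}
                    stale = 0
                else:
                    stale += 1
                    if stale >= self.early_stop_patience:
                        params = best_params or params
                        break
        self.params_ = params
        self.loss_trace_ = np.array(trace)
        self.fit_time_s_ = time.perf_counter() - t0
        self.n_steps_ = len(trace)
        return self

    def _scale(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.standardize:
            return (X - self.mean_) / self.std_
        return X

    def _loss_on(self, X, y, params, spec) -> float:
        logits, _ = self._forward(self._scale(X).astype(np.float32), params, spec)
        probs = softmax(logits)
        y_idx = np.searchsorted(self.classes_, np.asarray(y))
        return float(-np.log(probs[np.arange(len(y_idx)), y_idx] + 1e-12).mean())

    def decision_function(self, X):
        check_is_fitted(self, "params_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.model_spec_.n_bands:
            raise ValueError(
                f"expected {self.model_spec_.n_bands} bands, got {X.shape[1]}"
            )
        out = []
        for start in range(0, X.shape[0], 512):  # bound activation memory
            chunk = self._scale(X[start : start + 512]).astype(np.float32)
            logits, _ = self._forward(chunk, self.params_, self.model_spec_)
            out.append(logits)
        return np.vstack(out)

    def predict_proba(self, X):
        return softmax(self.decision_function(X))

    def predict(self, X):
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]


def ablate(configs: list[dict], X, y, plan, base_params: dict | None = None) -> pd.DataFrame:
    """Cross-validated comparison table over model configurations.

    ``configs`` is a list of keyword dicts for :class:`SpectralCNNClassifier`
    (e.g. ``{"variant": "cnn2c_se", "se_ratio": 8}``); ``plan`` is an
    evaluation FoldPlan. Returns one row per configuration with the
    mean +max/-min deviation columns of the standard report table.
    """
    from .evaluation import cross_validate

    rows = []
    for cfg in configs:
        kwargs = dict(base_params or {})
        kwargs.update(cfg)
        report = cross_validate(lambda kw=kwargs: SpectralCNNClassifier(**kw), X, y, plan)
        row = {"config": ", ".join(f"{k}={v}" for k, v in cfg.items())}
        row.update(report.summary_row())
        rows.append(row)
    return pd.DataFrame(rows)
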