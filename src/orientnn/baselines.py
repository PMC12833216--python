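"""Comparison architectures: frame-wise MLP, LSTM, CNN and Transformer.

All four consume the same per-frame input as the physics-informed model —
the seven sensor rotation matrices, flattened row-major in canonical sensor
order to a 63-feature vector (entries are direction cosines in [-1, 1]) —
and emit the same 12 joint-angle channels in degrees, so comparisons are
paired on identical data.

Architecture constants (hidden sizes, dropout, optimiser settings, loss
kind) are fixed per model:

=============  =====================================================  ====  ======
model          architecture                                           lr    loss
=============  =====================================================  ====  ======
mlp            63 -> 128 -> 128 -> 12, ReLU, dropout 0.2              0.01  L1
lstm           1-layer LSTM, 128 hidden, dropout 0.2, linear -> 12    0.01  L1
cnn            Conv2d(7ch, 64 filters, k=3, pad=1) + ReLU + dropout   0.01  Huber
               0.2 + flatten + linear -> 12
transformer    linear 9 -> 64, 3 encoder layers (d_model 64, 2 heads, 0.005 L1
               d_ff 256, dropout 0.1), flatten 7x64 -> linear -> 12
=============  =====================================================  ====  ======

All use Adam for 100 epochs with weight decay 1e-4. The sequence-capable
models operate frame-wise: the LSTM sees a singleton time axis, the
Transformer treats the seven sensors as its token axis (each token the nine
entries of that sensor's rotation matrix).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from . import autodiff as ad
from .model import _validate_frames

__all__ = [
    "BASELINE_SPECS",
    "BaselineNet",
    "flatten_features",
    "unflatten_features",
    "baseline_loss",
]

BASELINE_SPECS = {
    "mlp": dict(learning_rate=0.01, epochs=100, loss="l1", dropout=0.2,
                hidden=128, n_hidden_layers=2),
    "lstm": dict(learning_rate=0.01, epochs=100, loss="l1", dropout=0.2,
                 hidden=128),
    "cnn": dict(learning_rate=0.01, epochs=100, loss="huber", dropout=0.2,
                filters=64, kernel=3, pad=1),
    "transformer": dict(learning_rate=0.005, epochs=100, loss="l1",
                        dropout=0.1, d_model=64, n_layers=3, n_heads=2,
                        d_ff=256),
}

_WEIGHT_DECAY = 1e-4
_HUBER_DELTA = 1.0


def flatten_features(frame: np.ndarray) -> np.ndarray:
    """Flatten sensor orientations to the 63-feature vector(s).

    Row-major within each 3x3 matrix, sensors in canonical order.
    """
    X = _validate_frames(frame)
    flat = X.reshape(X.shape[0], 63)
    return flat[0] if np.asarray(frame).ndim == 3 else flat


def unflatten_features(vec: np.ndarray) -> np.ndarray:
    """Inverse of :func:`flatten_features`."""
    v = np.asarray(vec, dtype=float)
    single = v.ndim == 1
    v = np.atleast_2d(v)
    if v.shape[1] != 63:
        raise ValueError(f"expected 63 features, got {v.shape[1]}")
    out = v.reshape(-1, 7, 3, 3)
    return out[0] if single else out


def baseline_loss(kind: str, pred, target) -> ad.Tensor | float:
    """Training objective per model family: mean L1, or Huber (delta=1)."""
    tensor_in = isinstance(pred, ad.Tensor)
    p = pred if tensor_in else ad.constant(np.asarray(pred, float))
    t = target if isinstance(target, ad.Tensor) else ad.constant(np.asarray(target, float))
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    spec_loss = BASELINE_SPECS[kind]["loss"] if kind in BASELINE_SPECS else kind
    if spec_loss == "l1":
        out = ad.mean_all(ad.absolute(p - t))
    elif spec_loss == "huber":
        out = ad.huber_mean(p - t, delta=_HUBER_DELTA)
    else:
        raise ValueError(f"unknown loss kind {kind!r}")
    return out if tensor_in else out.item()


def _linear_init(rng, fan_in, fan_out, prefix):
    """Kaiming-uniform style init, matching common deep-learning defaults."""
    bound = 1.0 / np.sqrt(fan_in)
    W = ad.parameter(rng.uniform(-bound, bound, (fan_out, fan_in)), name=f"{prefix}.W")
    b = ad.parameter(rng.uniform(-bound, bound, fan_out), name=f"{prefix}.b")
    return W, b


def _linear(x, W, b):
    return x @ ad.transpose(W) + b


def _conv_gather_matrix() -> np.ndarray:
    """im2col gather for a 3x3 'image' with 7 channels, k=3, pad=1.

    Returns (9, 63, 63): for each of the nine output positions, a 0/1 matrix
    mapping the flattened (7, 3, 3) input to the flattened (7, 3, 3) patch.
    Convolution then reduces to a batched matrix product.
    """
    G = np.zeros((9, 63, 63))
    for oi in range(3):
        for oj in range(3):
            p = oi * 3 + oj
            for c in range(7):
                for ki in range(3):
                    for kj in range(3):
                        si, sj = oi + ki - 1, oj + kj - 1
                        if 0 <= si < 3 and 0 <= sj < 3:
                            G[p, c * 9 + ki * 3 + kj, c * 9 + si * 3 + sj] = 1.0
    return G


class BaselineNet(RegressorMixin, BaseEstimator):
    """Frame-wise neural baseline regressor (kind in mlp/lstm/cnn/transformer).

    Shares the estimator interface of :class:`~orientnn.model.OrientationNN`:
    ``X`` is (n, 7, 3, 3) or (n, 63); ``y`` is (n, 12) degrees. Dropout is
    active only during fit; prediction is deterministic.
    """

    def __init__(self, kind: str = "mlp", learning_rate: float | None = None,
                 epochs: int | None = None, batch_size: int = 256,
                 weight_decay: float = _WEIGHT_DECAY, random_state=None,
                 verbose: int = 0):
        self.kind = kind
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.weight_decay = weight_decay
        self.random_state = random_state
        self.verbose = verbose

    # -- construction -----------------------------------------------------
    def build(self) -> "BaselineNet":
        if self.kind not in BASELINE_SPECS:
            raise ValueError(
                f"unknown baseline kind {self.kind!r}; expected one of "
                f"{sorted(BASELINE_SPECS)}"
            )
        spec = BASELINE_SPECS[self.kind]
        rng = np.random.default_rng(self.random_state)
        P: dict[str, ad.Tensor] = {}
        if self.kind == "mlp":
            P["fc1.W"], P["fc1.b"] = _linear_init(rng, 63, 128, "fc1")
            P["fc2.W"], P["fc2.b"] = _linear_init(rng, 128, 128, "fc2")
            P["out.W"], P["out.b"] = _linear_init(rng, 128, 12, "out")
        elif self.kind == "lstm":
            H = spec["hidden"]
            bound = 1.0 / np.sqrt(H)
            P["lstm.weight_ih"] = ad.parameter(
                rng.uniform(-bound, bound, (4 * H, 63)), name="lstm.weight_ih")
            P["lstm.weight_hh"] = ad.parameter(
                rng.uniform(-bound, bound, (4 * H, H)), name="lstm.weight_hh")
            P["lstm.bias_ih"] = ad.parameter(
                rng.uniform(-bound, bound, 4 * H), name="lstm.bias_ih")
            P["lstm.bias_hh"] = ad.parameter(
                rng.uniform(-bound, bound, 4 * H), name="lstm.bias_hh")
            P["out.W"], P["out.b"] = _linear_init(rng, H, 12, "out")
        elif self.kind == "cnn":
            F = spec["filters"]
            P["conv.W"] = ad.parameter(
                rng.uniform(-1 / np.sqrt(63), 1 / np.sqrt(63), (F, 63)),
                name="conv.W")  # (filters, 7*3*3 patch)
            P["conv.b"] = ad.parameter(
                rng.uniform(-1 / np.sqrt(63), 1 / np.sqrt(63), F), name="conv.b")
            P["out.W"], P["out.b"] = _linear_init(rng, F * 9, 12, "out")
            self._gather = _conv_gather_matrix()
        else:  # transformer
            D, L, FF = spec["d_model"], spec["n_layers"], spec["d_ff"]
            P["embed.W"], P["embed.b"] = _linear_init(rng, 9, D, "embed")
            for i in range(L):
                pre = f"layer{i}"
                P[f"{pre}.attn.in_proj.W"] = ad.parameter(
                    rng.uniform(-1 / 8, 1 / 8, (3 * D, D)), name=f"{pre}.attn.in_proj.W")
                P[f"{pre}.attn.in_proj.b"] = ad.parameter(
                    np.zeros(3 * D), name=f"{pre}.attn.in_proj.b")
                P[f"{pre}.attn.out.W"], P[f"{pre}.attn.out.b"] = _linear_init(
                    rng, D, D, f"{pre}.attn.out")
                P[f"{pre}.ff1.W"], P[f"{pre}.ff1.b"] = _linear_init(rng, D, FF, f"{pre}.ff1")
                P[f"{pre}.ff2.W"], P[f"{pre}.ff2.b"] = _linear_init(rng, FF, D, f"{pre}.ff2")
                for n in (1, 2):
                    P[f"{pre}.norm{n}.g"] = ad.parameter(np.ones(D), name=f"{pre}.norm{n}.g")
                    P[f"{pre}.norm{n}.b"] = ad.parameter(np.zeros(D), name=f"{pre}.norm{n}.b")
            P["out.W"], P["out.b"] = _linear_init(rng, 7 * D, 12, "out")
        self.params_ = P
        self.n_parameters_ = sum(p.size for p in P.values())
        self.loss_history_ = {"train": [], "val": []}
        return self

    # -- forward ----------------------------------------------------------
    def _dropout(self, x: ad.Tensor, rate: float, rng) -> ad.Tensor:
        if rng is None or rate <= 0:
            return x
        mask = (rng.random(x.shape) >= rate) / (1.0 - rate)
        return x * ad.constant(mask)

    def _forward(self, X: np.ndarray, rng=None) -> ad.Tensor:
        """Forward pass; ``rng`` enables dropout (training mode)."""
        spec = BASELINE_SPECS[self.kind]
        P = self.params_
        flat = ad.constant(X.reshape(X.shape[0], 63))
        if self.kind == "mlp":
            h = self._dropout(ad.relu(_linear(flat, P["fc1.W"], P["fc1.b"])), spec["dropout"], rng)
            h = self._dropout(ad.relu(_linear(h, P["fc2.W"], P["fc2.b"])), spec["dropout"], rng)
            return _linear(h, P["out.W"], P["out.b"])
        if self.kind == "lstm":
            H = spec["hidden"]
            gates = (flat @ ad.transpose(P["lstm.weight_ih"])
                     + P["lstm.bias_ih"] + P["lstm.bias_hh"])  # h0 = c0 = 0
            i = ad.sigmoid(gates[:, 0:H])
            g = ad.tanh(gates[:, 2 * H:3 * H])
            o = ad.sigmoid(gates[:, 3 * H:4 * H])
            c = i * g  # forget gate idles against c0 = 0
            h = self._dropout(o * ad.tanh(c), spec["dropout"], rng)
            return _linear(h, P["out.W"], P["out.b"])
        if self.kind == "cnn":
            xb = ad.reshape(flat, (X.shape[0], 1, 63, 1))
            patches = ad.matmul(ad.constant(self._gather), xb)  # (n, 9, 63, 1)
            patches = ad.reshape(patches, (X.shape[0], 9, 63))
            fmap = ad.matmul(patches, ad.transpose(P["conv.W"])) + P["conv.b"]
            h = self._dropout(ad.relu(fmap), spec["dropout"], rng)
            h = ad.reshape(h, (X.shape[0], 9 * spec["filters"]))
            return _linear(h, P["out.W"], P["out.b"])
        # transformer
        D, nh = spec["d_model"], spec["n_heads"]
        dk = D // nh
        tokens = ad.reshape(flat, (X.shape[0], 7, 9))
        x = _linear(tokens, P["embed.W"], P["embed.b"])
        for li in range(spec["n_layers"]):
            pre = f"layer{li}"
            qkv = _linear(x, P[f"{pre}.attn.in_proj.W"], P[f"{pre}.attn.in_proj.b"])
            q, k, v = qkv[..., 0:D], qkv[..., D:2 * D], qkv[..., 2 * D:3 * D]

            def heads(z):
                z = ad.reshape(z, (X.shape[0], 7, nh, dk))
                return ad.transpose(z, (0, 2, 1, 3))

            qh, kh, vh = heads(q), heads(k), heads(v)
            scores = ad.matmul(qh, ad.transpose(kh)) * (1.0 / np.sqrt(dk))
            attn = self._dropout(ad.softmax(scores, axis=-1), spec["dropout"], rng)
            ctx = ad.transpose(ad.matmul(attn, vh), (0, 2, 1, 3))
            ctx = ad.reshape(ctx, (X.shape[0], 7, D))
            ctx = self._dropout(
                _linear(ctx, P[f"{pre}.attn.out.W"], P[f"{pre}.attn.out.b"]),
                spec["dropout"], rng)
            x = _layernorm(x + ctx, P[f"{pre}.norm1.g"], P[f"{pre}.norm1.b"])
            ff = _linear(self._dropout(ad.relu(
                _linear(x, P[f"{pre}.ff1.W"], P[f"{pre}.ff1.b"])),
                spec["dropout"], rng), P[f"{pre}.ff2.W"], P[f"{pre}.ff2.b"])
            x = _layernorm(x + self._dropout(ff, spec["dropout"], rng),
                           P[f"{pre}.norm2.g"], P[f"{pre}.norm2.b"])
        h = ad.reshape(x, (X.shape[0], 7 * D))
        return _linear(h, P["out.W"], P["out.b"])

    # -- sklearn API ------------------------------------------------------
    def fit(self, X, y, validation_data=None):
        X = _validate_frames(X)
        y = np.asarray(y, dtype=float)
        if X.shape[0] != y.shape[0] or y.ndim != 2 or y.shape[1] != 12:
            raise ValueError("y must be (n, 12) and match X")
        self.build()
        spec = BASELINE_SPECS[self.kind]
        lr = spec["learning_rate"] if self.learning_rate is None else self.learning_rate
        epochs = spec["epochs"] if self.epochs is None else self.epochs
        rng = np.random.default_rng(
            None if self.random_state is None else self.random_state + 1
        )
        opt = ad.Adam(list(self.params_.values()), lr=lr,
                      weight_decay=self.weight_decay)
        n = X.shape[0]
        for epoch in range(epochs):
            order = rng.permutation(n)
            batch_losses = []
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                pred = self._forward(X[idx], rng=rng)
                loss = baseline_loss(self.kind, pred, ad.constant(y[idx]))
                if not np.isfinite(loss.item()):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch + 1}, batch at {start}"
                    )
                opt.zero_grad()
                loss.backward()
                opt.step()
                batch_losses.append(loss.item())
            self.loss_history_["train"].append(float(np.mean(batch_losses)))
            if validation_data is not None:
                Xv, yv = validation_data
                self.loss_history_["val"].append(
                    baseline_loss(self.kind, self.predict(Xv), yv)
                )
            if self.verbose:
                print(f"[{self.kind}] epoch {epoch + 1}/{epochs} "
                      f"train {self.loss_history_['train'][-1]:.4f}")
        self.n_features_in_ = 63
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "params_")
        X = _validate_frames(X)
        return self._forward(X, rng=None).data

    # -- parameter interchange --------------------------------------------
    def params_dict(self) -> dict[str, np.ndarray]:
        check_is_fitted(self, "params_")
        return {k: p.data.copy() for k, p in self.params_.items()}

    def load_params(self, params: dict[str, np.ndarray]) -> "BaselineNet":
        if not hasattr(self, "params_"):
            self.build()
        for k, p in self.params_.items():
            if k not in params:
                raise KeyError(f"checkpoint missing parameter {k}")
            p.data = np.asarray(params[k], dtype=float).reshape(p.shape).copy()
        return self


def _layernorm(x: ad.Tensor, g: ad.Tensor, b: ad.Tensor, eps: float = 1e-5) -> ad.Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    return xc / ad.sqrt(var + eps) * g + b
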