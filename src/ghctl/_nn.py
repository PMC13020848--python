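"""Minimal seeded neural-network core: MLP and Conv1D+LSTM with MAE loss.

The surrogate estimators train with a mean-absolute-error objective, which is
not available in scikit-learn's neural models, so the two small architectures
used in this package are implemented directly on numpy with hand-written
backpropagation and an Adam optimizer.  Gradients are verified against finite
differences in the test suite.

Shapes: dense inputs are ``(batch, features)``; sequence inputs are
``(batch, time, features)``.
"""

from __future__ import annotations

import numpy as np


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[0] if len(shape) == 2 else int(np.prod(shape[:-1])), shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def mae(pred: np.ndarray, target: np.ndarray) -> float:
    return float(np.mean(np.abs(pred - target)))


def _mae_grad(pred: np.ndarray, target: np.ndarray) -> np.ndarray:
    return np.sign(pred - target) / pred.size


class MLP:
    """Feed-forward network with ReLU hidden layers and a linear head."""

    def __init__(self, sizes: list[int], seed: int = 0):
        if len(sizes) < 2:
            raise ValueError("need at least input and output sizes")
        rng = np.random.default_rng(seed)
        self.sizes = list(sizes)
        self.params: dict[str, np.ndarray] = {}
        for i in range(len(sizes) - 1):
            self.params[f"W{i}"] = _glorot(rng, (sizes[i], sizes[i + 1]))
            self.params[f"b{i}"] = np.zeros(sizes[i + 1])
        self.n_layers = len(sizes) - 1

    def forward(self, x: np.ndarray):
        acts = [x]
        for i in range(self.n_layers):
            z = acts[-1] @ self.params[f"W{i}"] + self.params[f"b{i}"]
            acts.append(np.maximum(z, 0.0) if i < self.n_layers - 1 else z)
        return acts[-1], acts

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)[0]

    def backward(self, acts: list[np.ndarray], d_out: np.ndarray):
        grads: dict[str, np.ndarray] = {}
        delta = d_out
        for i in range(self.n_layers - 1, -1, -1):
            grads[f"W{i}"] = acts[i].T @ delta
            grads[f"b{i}"] = delta.sum(axis=0)
            if i > 0:
                delta = (delta @ self.params[f"W{i}"].T) * (acts[i] > 0)
        return grads

    def loss_and_grads(self, x: np.ndarray, y: np.ndarray):
        pred, acts = self.forward(x)
        return mae(pred, y), self.backward(acts, _mae_grad(pred, y))

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p in self.params.values())


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -40.0, 40.0)))


class SequenceNet:
    """1-D convolutional front-end + LSTM + linear head.

    The convolution (``valid`` padding along time) extracts local temporal
    features; a single LSTM layer summarizes the sequence; the head reads the
    final hidden state.
    """

    def __init__(self, n_features: int, n_out: int, conv_channels: int = 16,
                 kernel: int = 3, hidden: int = 32, seed: int = 0):
        if kernel < 1 or conv_channels < 1 or hidden < 1:
            raise ValueError("conv/lstm sizes must be positive")
        rng = np.random.default_rng(seed)
        self.kernel, self.channels, self.hidden = kernel, conv_channels, hidden
        self.params = {
            "Wc": _glorot(rng, (kernel, n_features, conv_channels)),
            "bc": np.zeros(conv_channels),
            "Wx": _glorot(rng, (conv_channels, 4 * hidden)),
            "Wh": _glorot(rng, (hidden, 4 * hidden)),
            "bl": np.zeros(4 * hidden),
            "Wo": _glorot(rng, (hidden, n_out)),
            "bo": np.zeros(n_out),
        }
        # forget-gate bias at 1 for stable early training
        self.params["bl"][hidden:2 * hidden] = 1.0

    def _conv(self, x: np.ndarray) -> np.ndarray:
        B, T, _ = x.shape
        Tc = T - self.kernel + 1
        if Tc < 1:
            raise ValueError(
                f"sequence length {T} shorter than kernel {self.kernel}")
        z = np.broadcast_to(self.params["bc"],
                            (B, Tc, self.channels)).copy()
        for k in range(self.kernel):
            z += x[:, k:k + Tc, :] @ self.params["Wc"][k]
        return z

    def forward(self, x: np.ndarray):
        B = x.shape[0]
        H = self.hidden
        zc = self._conv(x)
        c_act = np.maximum(zc, 0.0)
        Tc = c_act.shape[1]
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        cache = {"x": x, "zc": zc, "c_act": c_act, "steps": []}
        for t in range(Tc):
            gates = (c_act[:, t, :] @ self.params["Wx"]
                     + h @ self.params["Wh"] + self.params["bl"])
            i = _sigmoid(gates[:, :H])
            f = _sigmoid(gates[:, H:2 * H])
            o = _sigmoid(gates[:, 2 * H:3 * H])
            g = np.tanh(gates[:, 3 * H:])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            cache["steps"].append((h, c, i, f, o, g, c_new, tc))
            h, c = h_new, c_new
        cache["h_last"] = h
        out = h @ self.params["Wo"] + self.params["bo"]
        return out, cache

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)[0]

    def backward(self, cache, d_out: np.ndarray):
        H = self.hidden
        p = self.params
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        grads["Wo"] = cache["h_last"].T @ d_out
        grads["bo"] = d_out.sum(axis=0)
        dh = d_out @ p["Wo"].T
        dc = np.zeros_like(dh)
        c_act = cache["c_act"]
        d_cact = np.zeros_like(c_act)
        for t in range(len(cache["steps"]) - 1, -1, -1):
            h_prev, c_prev, i, f, o, g, c_new, tc = cache["steps"][t]
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc * tc)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dgates = np.concatenate([
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                do * o * (1.0 - o),
                dg * (1.0 - g * g),
            ], axis=1)
            grads["Wx"] += c_act[:, t, :].T @ dgates
            grads["Wh"] += h_prev.T @ dgates
            grads["bl"] += dgates.sum(axis=0)
            d_cact[:, t, :] = dgates @ p["Wx"].T
            dh = dgates @ p["Wh"].T
            dc = dc * f
        dzc = d_cact * (cache["zc"] > 0)
        grads["bc"] = dzc.sum(axis=(0, 1))
        Tc = dzc.shape[1]
        x = cache["x"]
        for k in range(self.kernel):
            grads["Wc"][k] = np.einsum("btf,btc->fc", x[:, k:k + Tc, :], dzc)
        return grads

    def loss_and_grads(self, x: np.ndarray, y: np.ndarray):
        pred, cache = self.forward(x)
        return mae(pred, y), self.backward(cache, _mae_grad(pred, y))

    @property
    def n_parameters(self) -> int:
        return sum(v.size for v in self.params.values())


class Adam:
    """Adam optimizer over a model's named-parameter dict."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1.0 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1.0 - self.b2) * g * g
            self.params[k] -= (self.lr * (self.m[k] / bc1)
                               / (np.sqrt(self.v[k] / bc2) + self.eps))


def fit(model, x: np.ndarray, y: np.ndarray, *, epochs: int = 50,
        batch_size: int = 64, lr: float = 1e-3, seed: int = 0,
        x_val: np.ndarray | None = None, y_val: np.ndarray | None = None,
        verbose: bool = False) -> dict:
    """Mini-batch MAE training loop; returns per-epoch loss history."""
    rng = np.random.default_rng(seed)
    n = len(x)
    opt = Adam(model.params, lr=lr)
    history: dict[str, list[float]] = {"train": [], "val": []}
    for epoch in range(epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            loss, grads = model.loss_and_grads(x[idx], y[idx])
            opt.step(grads)
            losses.append(loss)
        history["train"].append(float(np.mean(losses)))
        if x_val is not None:
            history["val"].append(mae(model.predict(x_val), y_val))
        if verbose:
            val = history["val"][-1] if history["val"] else float("nan")
            print(f"epoch {epoch + 1:3d}  train {history['train'][-1]:.4f}"
                  f"  val {val:.4f}")
    return history
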