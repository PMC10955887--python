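"""Minimal NumPy sequence classifiers: a two-layer LSTM and a temporal CNN.

Both are trained with mini-batch Adam on the categorical cross-entropy
loss (batch size 32 by default) and use inverted dropout (rate 0.2) before
the softmax head.  Gradients are hand-derived and verified against
numerical differentiation in the test suite.  All randomness (weight
initialization, batch shuffling, dropout masks) flows from the seed, so a
fit is bit-reproducible.

The LSTM stacks two recurrent layers; the hidden sequence passed upward is
rectified (ReLU) while the state carried along time is the raw LSTM
output.  Classification reads the last timestep.  The CNN convolves over
the time axis with neurons as input channels: two conv(kernel 3)+ReLU+
max-pool(2) blocks, dropout, then a dense softmax layer.
"""

from __future__ import annotations

import numpy as np

from .errors import InsufficientDataError, InvalidParameterError, ShapeError

__all__ = ["LSTMClassifier", "CNNClassifier"]


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape or (fan_in, fan_out))


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class _LSTMLayer:
    """Single LSTM layer operating on (batch, time, features)."""

    def __init__(self, rng: np.random.Generator, n_in: int, n_hidden: int, prefix: str):
        self.h = n_hidden
        self.prefix = prefix
        self.params = {
            f"{prefix}Wx": _glorot(rng, n_in, 4 * n_hidden),
            f"{prefix}Wh": _glorot(rng, n_hidden, 4 * n_hidden),
            f"{prefix}b": np.zeros(4 * n_hidden),
        }
        # forget-gate bias starts at 1 (standard trick for gradient flow)
        self.params[f"{prefix}b"][n_hidden : 2 * n_hidden] = 1.0

    def forward(self, x: np.ndarray):
        p = self.params
        wx, wh, b = p[f"{self.prefix}Wx"], p[f"{self.prefix}Wh"], p[f"{self.prefix}b"]
        bsz, steps, _ = x.shape
        hdim = self.h
        h = np.zeros((bsz, hdim))
        c = np.zeros((bsz, hdim))
        hs = np.empty((bsz, steps, hdim))
        cache = []
        for t in range(steps):
            z = x[:, t] @ wx + h @ wh + b
            i = 1.0 / (1.0 + np.exp(-z[:, :hdim]))
            f = 1.0 / (1.0 + np.exp(-z[:, hdim : 2 * hdim]))
            g = np.tanh(z[:, 2 * hdim : 3 * hdim])
            o = 1.0 / (1.0 + np.exp(-z[:, 3 * hdim :]))
            c_new = f * c + i * g
            hc = np.tanh(c_new)
            h_new = o * hc
            cache.append((x[:, t], h, c, i, f, g, o, c_new, hc))
            h, c = h_new, c_new
            hs[:, t] = h
        return hs, cache

    def backward(self, dhs: np.ndarray, cache) -> tuple[np.ndarray, dict[str, np.ndarray]]:
        p = self.params
        wx, wh = p[f"{self.prefix}Wx"], p[f"{self.prefix}Wh"]
        bsz, steps, hdim = dhs.shape
        dwx = np.zeros_like(wx)
        dwh = np.zeros_like(wh)
        db = np.zeros(4 * hdim)
        dx = np.empty((bsz, steps, wx.shape[0]))
        dh_next = np.zeros((bsz, hdim))
        dc_next = np.zeros((bsz, hdim))
        for t in range(steps - 1, -1, -1):
            xt, h_prev, c_prev, i, f, g, o, c_new, hc = cache[t]
            dh = dhs[:, t] + dh_next
            dc = dh * o * (1 - hc**2) + dc_next
            do = dh * hc
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dg * (1 - g**2),
                    do * o * (1 - o),
                ],
                axis=1,
            )
            dwx += xt.T @ dz
            dwh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, t] = dz @ wx.T
            dh_next = dz @ wh.T
            dc_next = dc * f
        grads = {f"{self.prefix}Wx": dwx, f"{self.prefix}Wh": dwh, f"{self.prefix}b": db}
        return dx, grads


class _BaseClassifier:
    """Shared fit loop: mini-batch Adam on cross-entropy."""

    def __init__(self, lr: float, epochs: int, batch_size: int, dropout: float, seed: int):
        if not 0 <= dropout < 1:
            raise InvalidParameterError(f"dropout must be in [0, 1), got {dropout}")
        self.lr = lr
        self.epochs = epochs
        self.batch_size = batch_size
        self.dropout = dropout
        self.seed = seed
        self.classes_: np.ndarray | None = None
        self.loss_history_: list[float] = []

    def _encode_labels(self, y) -> np.ndarray:
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        lut = {c: i for i, c in enumerate(self.classes_.tolist())}
        return np.asarray([lut[v] for v in y.tolist()], dtype=np.int64)

    def fit(self, x: np.ndarray, y) -> "_BaseClassifier":
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 3:
            raise ShapeError("expected input of shape (samples, frames, features)")
        if x.shape[0] < 2:
            raise InsufficientDataError("need at least 2 training samples")
        yi = self._encode_labels(y)
        rng = np.random.default_rng(self.seed)
        self._build(rng, x.shape[1], x.shape[2], self.classes_.size)
        opt = _Adam(self.params, self.lr)
        n = x.shape[0]
        for _ in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                sel = order[start : start + self.batch_size]
                loss, grads = self._loss_and_grads(x[sel], yi[sel], rng)
                opt.step(grads)
                epoch_loss += loss * sel.size
            self.loss_history_.append(epoch_loss / n)
        return self

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        single = x.ndim == 2
        if single:
            x = x[None]
        logits = self._forward_logits(x, train_rng=None)
        probs = _softmax(logits)
        return probs[0] if single else probs

    def predict(self, x: np.ndarray):
        probs = self.predict_proba(x)
        if probs.ndim == 1:
            return self.classes_[int(np.argmax(probs))]
        return self.classes_[np.argmax(probs, axis=1)]

    # subclass interface -------------------------------------------------
    def _build(self, rng, n_frames: int, n_features: int, n_classes: int) -> None:
        raise NotImplementedError

    def _forward_logits(self, x, train_rng):
        raise NotImplementedError

    def _loss_and_grads(self, xb, yb, rng):
        raise NotImplementedError


class LSTMClassifier(_BaseClassifier):
    """Two-layer LSTM over short windows of population activity."""

    def __init__(self, hidden: int = 32, lr: float = 1e-3, epochs: int = 20,
                 batch_size: int = 32, dropout: float = 0.2, seed: int = 0):
        super().__init__(lr, epochs, batch_size, dropout, seed)
        self.hidden = hidden

    def _build(self, rng, n_frames, n_features, n_classes):
        self.l1 = _LSTMLayer(rng, n_features, self.hidden, "l1_")
        self.l2 = _LSTMLayer(rng, self.hidden, self.hidden, "l2_")
        self.params = {**self.l1.params, **self.l2.params}
        self.params["Wd"] = _glorot(rng, self.hidden, n_classes)
        self.params["bd"] = np.zeros(n_classes)
        self.l1.params = self.params
        self.l2.params = self.params

    def _forward(self, x, train_rng):
        h1, c1 = self.l1.forward(x)
        a1 = np.maximum(h1, 0.0)
        h2, c2 = self.l2.forward(a1)
        last = np.maximum(h2[:, -1], 0.0)
        if train_rng is not None and self.dropout > 0:
            keep = 1.0 - self.dropout
            mask = (train_rng.random(last.shape) < keep) / keep
            feat = last * mask
        else:
            mask = None
            feat = last
        logits = feat @ self.params["Wd"] + self.params["bd"]
        return logits, (x, h1, c1, a1, h2, c2, last, mask, feat)

    def _forward_logits(self, x, train_rng):
        return self._forward(x, train_rng)[0]

    def _loss_and_grads(self, xb, yb, rng):
        logits, cache = self._forward(xb, rng)
        x, h1, c1, a1, h2, c2, last, mask, feat = cache
        bsz = xb.shape[0]
        probs = _softmax(logits)
        loss = -float(np.mean(np.log(probs[np.arange(bsz), yb] + 1e-12)))
        dlogits = probs
        dlogits[np.arange(bsz), yb] -= 1.0
        dlogits /= bsz
        grads = {
            "Wd": feat.T @ dlogits,
            "bd": dlogits.sum(axis=0),
        }
        dfeat = dlogits @ self.params["Wd"].T
        if mask is not None:
            dfeat = dfeat * mask
        dlast = dfeat * (h2[:, -1] > 0)
        dh2 = np.zeros_like(h2)
        dh2[:, -1] = dlast
        da1, g2 = self.l2.backward(dh2, c2)
        dh1 = da1 * (h1 > 0)
        _, g1 = self.l1.backward(dh1, c1)
        grads.update(g1)
        grads.update(g2)
        return loss, grads


class CNNClassifier(_BaseClassifier):
    """Temporal CNN over stimulus epochs (conv over time, neurons as channels)."""

    def __init__(self, filters: int = 32, kernel: int = 3, pool: int = 2,
                 lr: float = 1e-3, epochs: int = 20, batch_size: int = 32,
                 dropout: float = 0.2, seed: int = 0):
        super().__init__(lr, epochs, batch_size, dropout, seed)
        self.filters = filters
        self.kernel = kernel
        self.pool = pool

    # -- conv helpers ----------------------------------------------------
    @staticmethod
    def _im2col(x: np.ndarray, k: int) -> np.ndarray:
        # x: (B, T, C) -> (B, T-k+1, k*C)
        bsz, t, c = x.shape
        out_t = t - k + 1
        cols = np.empty((bsz, out_t, k * c))
        for j in range(k):
            cols[:, :, j * c : (j + 1) * c] = x[:, j : j + out_t]
        return cols

    def _conv_forward(self, x, w, b):
        cols = self._im2col(x, self.kernel)
        out = cols @ w + b
        return out, cols

    def _conv_backward(self, dout, cols, x_shape, w):
        dw = np.einsum("btk,btf->kf", cols, dout)
        db = dout.sum(axis=(0, 1))
        dcols = dout @ w.T
        bsz, t, c = x_shape
        dx = np.zeros((bsz, t, c))
        out_t = t - self.kernel + 1
        for j in range(self.kernel):
            dx[:, j : j + out_t] += dcols[:, :, j * c : (j + 1) * c]
        return dx, dw, db

    def _pool_forward(self, x):
        bsz, t, c = x.shape
        t2 = (t // self.pool) * self.pool
        xr = x[:, :t2].reshape(bsz, t2 // self.pool, self.pool, c)
        out = xr.max(axis=2)
        argmax = xr.argmax(axis=2)
        return out, (argmax, x.shape, t2)

    def _pool_backward(self, dout, cache):
        argmax, x_shape, t2 = cache
        bsz, t, c = x_shape
        dx = np.zeros((bsz, t, c))
        n_windows = t2 // self.pool
        bi, wi, ci = np.meshgrid(
            np.arange(bsz), np.arange(n_windows), np.arange(c), indexing="ij"
        )
        dx[bi, wi * self.pool + argmax, ci] = dout
        return dx

    # -- model -----------------------------------------------------------
    def _build(self, rng, n_frames, n_features, n_classes):
        min_t = self.kernel
        t1 = (n_frames - self.kernel + 1) // self.pool
        t2 = (t1 - self.kernel + 1) // self.pool
        if t2 < 1:
            raise InsufficientDataError(
                f"epoch of {n_frames} frames too short for two conv/pool blocks"
            )
        k, f = self.kernel, self.filters
        self.params = {
            "W1": _glorot(rng, k * n_features, f),
            "b1": np.zeros(f),
            "W2": _glorot(rng, k * f, f),
            "b2": np.zeros(f),
            "Wd": _glorot(rng, t2 * f, n_classes),
            "bd": np.zeros(n_classes),
        }
        self._flat_dim = t2 * f

    def _forward(self, x, train_rng):
        p = self.params
        z1, cols1 = self._conv_forward(x, p["W1"], p["b1"])
        a1 = np.maximum(z1, 0.0)
        p1, pc1 = self._pool_forward(a1)
        z2, cols2 = self._conv_forward(p1, p["W2"], p["b2"])
        a2 = np.maximum(z2, 0.0)
        p2, pc2 = self._pool_forward(a2)
        flat = p2.reshape(x.shape[0], -1)
        if train_rng is not None and self.dropout > 0:
            keep = 1.0 - self.dropout
            mask = (train_rng.random(flat.shape) < keep) / keep
            feat = flat * mask
        else:
            mask = None
            feat = flat
        logits = feat @ p["Wd"] + p["bd"]
        cache = (x, cols1, z1, pc1, p1, cols2, z2, pc2, p2, mask, feat)
        return logits, cache

    def _forward_logits(self, x, train_rng):
        return self._forward(x, train_rng)[0]

    def _loss_and_grads(self, xb, yb, rng):
        logits, cache = self._forward(xb, rng)
        x, cols1, z1, pc1, p1, cols2, z2, pc2, p2, mask, feat = cache
        bsz = xb.shape[0]
        probs = _softmax(logits)
        loss = -float(np.mean(np.log(probs[np.arange(bsz), yb] + 1e-12)))
        dlogits = probs
        dlogits[np.arange(bsz), yb] -= 1.0
        dlogits /= bsz
        p = self.params
        grads = {"Wd": feat.T @ dlogits, "bd": dlogits.sum(axis=0)}
        dfeat = dlogits @ p["Wd"].T
        if mask is not None:
            dfeat = dfeat * mask
        dp2 = dfeat.reshape(p2.shape)
        da2 = self._pool_backward(dp2, pc2)
        dz2 = da2 * (z2 > 0)
        dp1, dw2, db2 = self._conv_backward(dz2, cols2, p1.shape, p["W2"])
        grads["W2"], grads["b2"] = dw2, db2
        da1 = self._pool_backward(dp1, pc1)
        dz1 = da1 * (z1 > 0)
        _, dw1, db1 = self._conv_backward(dz1, cols1, x.shape, p["W1"])
        grads["W1"], grads["b1"] = dw1, db1
        return loss, grads
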