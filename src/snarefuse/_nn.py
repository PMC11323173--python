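"""Minimal NumPy neural-network engine used by the fusion model.

Implements exactly the layers the hybrid architecture needs — hashed
n-gram embedding, 1-D convolution bank, RBF kernel layer, LSTM / simple
RNN cells, dense head — with hand-derived reverse-mode gradients and an
Adam optimizer.  Everything operates on batch-major float64 arrays with an
explicit per-position validity mask so variable-length sequences can share
a padded batch.

Conventions
-----------
* activations: ``(B, M, D)``; masks: ``(B, M)`` with 1.0 on real positions.
* each layer stores its forward cache and accumulates parameter gradients
  in ``grads`` during ``backward``; ``zero_grads`` resets them.
* all randomness (init, dropout) flows through ``numpy.random.Generator``
  objects supplied by the caller, so a seed fully determines behaviour.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np


def relu(x):
    """Elementwise max(0, x)."""
    return np.maximum(0.0, np.asarray(x, dtype=float))


def softmax(z, axis=-1):
    """Numerically safe softmax (max-subtraction); rows sum to 1."""
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("softmax input must be finite")
    shifted = z - z.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=axis, keepdims=True)


def sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    """Base: holds params and accumulated grads keyed by name."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def zero_grads(self) -> None:
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}


class NgramEmbedding(Layer):
    """Learnable hash-bucket table; output = mean of rows of the n-grams
    ending at each position (ids -1 mark absent n-grams)."""

    def __init__(self, buckets: int, dim: int, rng: np.random.Generator):
        super().__init__()
        self.buckets, self.dim = buckets, dim
        self.params["table"] = rng.normal(0.0, 1.0 / np.sqrt(dim),
                                          size=(buckets, dim))
        self.zero_grads()

    def forward(self, ids: np.ndarray) -> np.ndarray:
        valid = ids >= 0                                   # (B, M, G)
        safe = np.where(valid, ids, 0)
        cnt = np.maximum(valid.sum(axis=-1), 1)            # (B, M)
        rows = self.params["table"][safe] * valid[..., None]
        out = rows.sum(axis=2) / cnt[..., None]
        self._cache = (safe, valid, cnt)
        return out

    def backward(self, dout: np.ndarray) -> None:
        safe, valid, cnt = self._cache
        w = dout[:, :, None, :] * (valid / cnt[..., None])[..., None]
        np.add.at(self.grads["table"], safe[valid], w[valid])


class Dense(Layer):
    """Affine map on the last axis."""

    def __init__(self, din: int, dout: int, rng: np.random.Generator):
        super().__init__()
        self.params["W"] = _glorot(rng, din, dout, (din, dout))
        self.params["b"] = np.zeros(dout)
        self.zero_grads()

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._x
        xf = x.reshape(-1, x.shape[-1])
        df = dout.reshape(-1, dout.shape[-1])
        self.grads["W"] += xf.T @ df
        self.grads["b"] += df.sum(axis=0)
        return dout @ self.params["W"].T


class ConvBank(Layer):
    """Parallel same-padded 1-D convolutions (one weight set per kernel
    size), each followed by ReLU and (in training) inverted dropout;
    outputs are concatenated per position."""

    def __init__(self, din: int, num_filters: int,
                 kernel_sizes: Sequence[int], dropout_rate: float,
                 rng: np.random.Generator):
        super().__init__()
        self.din = din
        self.num_filters = num_filters
        self.kernel_sizes = list(kernel_sizes)
        self.dropout_rate = float(dropout_rate)
        for k in self.kernel_sizes:
            if k % 2 != 1:
                raise ValueError("kernel sizes must be odd (same padding)")
            self.params[f"W{k}"] = _glorot(rng, k * din, num_filters,
                                           (k * din, num_filters))
            self.params[f"b{k}"] = np.zeros(num_filters)
        self.zero_grads()

    @property
    def out_dim(self) -> int:
        return self.num_filters * len(self.kernel_sizes)

    def forward(self, x: np.ndarray, mask: np.ndarray, training: bool,
                rng: Optional[np.random.Generator] = None) -> np.ndarray:
        b, m, _ = x.shape
        outs, caches = [], []
        for k in self.kernel_sizes:
            pad = k // 2
            xp = np.zeros((b, m + 2 * pad, self.din))
            xp[:, pad:pad + m] = x * mask[:, :, None]
            win = np.concatenate([xp[:, j:j + m] for j in range(k)], axis=2)
            z = win @ self.params[f"W{k}"] + self.params[f"b{k}"]
            a = np.maximum(z, 0.0)
            if training and self.dropout_rate > 0.0:
                keep = (rng.random(a.shape) >= self.dropout_rate)
                a = a * keep / (1.0 - self.dropout_rate)
            else:
                keep = None
            a = a * mask[:, :, None]
            outs.append(a)
            caches.append((win, z, keep))
        self._cache = (caches, mask, (b, m))
        return np.concatenate(outs, axis=2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        caches, mask, (b, m) = self._cache
        dx = np.zeros((b, m, self.din))
        f = self.num_filters
        for i, k in enumerate(self.kernel_sizes):
            win, z, keep = caches[i]
            da = dout[:, :, i * f:(i + 1) * f] * mask[:, :, None]
            if keep is not None:
                da = da * keep / (1.0 - self.dropout_rate)
            dz = da * (z > 0)
            self.grads[f"W{k}"] += (
                win.reshape(-1, k * self.din).T @ dz.reshape(-1, f)
            )
            self.grads[f"b{k}"] += dz.reshape(-1, f).sum(axis=0)
            dwin = dz @ self.params[f"W{k}"].T
            pad = k // 2
            dxp = np.zeros((b, m + 2 * pad, self.din))
            for j in range(k):
                dxp[:, j:j + m] += dwin[:, :, j * self.din:(j + 1) * self.din]
            dx += dxp[:, pad:pad + m] * mask[:, :, None]
        return dx


class RBFLayer(Layer):
    """Kernel activations of the distance to k learnable centers.

    Gaussian: exp(-gamma * d^2) with gamma = exp(log_gamma);
    quadratic: 1 - d^2 / sigma with sigma = exp(log_sigma).
    Widths are stored on the log scale so they stay positive under Adam.
    """

    def __init__(self, dim: int, num_centers: int, kernel: str = "gaussian"):
        super().__init__()
        if kernel not in ("gaussian", "quadratic"):
            raise ValueError(f"unknown RBF kernel {kernel!r}")
        self.kernel = kernel
        self.dim, self.num_centers = dim, num_centers
        self.params["centers"] = np.zeros((num_centers, dim))
        self.params["log_width"] = np.zeros(1)
        self.zero_grads()

    def set_centers(self, centers: np.ndarray) -> None:
        centers = np.asarray(centers, dtype=float)
        if centers.shape != (self.num_centers, self.dim):
            raise ValueError("center array has wrong shape")
        self.params["centers"] = centers.copy()
        # median heuristic: width from the inter-center squared distances
        if self.num_centers > 1:
            d2 = ((centers[:, None] - centers[None]) ** 2).sum(-1)
            med = np.median(d2[np.triu_indices(self.num_centers, 1)])
            med = max(med, 1e-8)
            if self.kernel == "gaussian":
                self.params["log_width"] = np.array([np.log(1.0 / med)])
            else:
                self.params["log_width"] = np.array([np.log(med)])
        self.zero_grads()

    def forward(self, x: np.ndarray, mask: np.ndarray) -> np.ndarray:
        c = self.params["centers"]
        width = np.exp(self.params["log_width"][0])
        d2 = ((x ** 2).sum(-1, keepdims=True)
              + (c ** 2).sum(-1)[None, None, :]
              - 2.0 * (x @ c.T))
        d2 = np.maximum(d2, 0.0)
        if self.kernel == "gaussian":
            act = np.exp(-width * d2)
        else:
            act = 1.0 - d2 / width
        act = act * mask[:, :, None]
        self._cache = (x, d2, act, mask, width)
        return act

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, d2, act, mask, width = self._cache
        c = self.params["centers"]
        dout = dout * mask[:, :, None]
        if self.kernel == "gaussian":
            dd2 = -width * act * dout
            self.grads["log_width"][0] += float(
                (dout * act * (-d2)).sum()) * width
        else:
            dd2 = -dout / width
            self.grads["log_width"][0] += float((dout * d2).sum()) / width
        dx = 2.0 * (dd2.sum(-1, keepdims=True) * x - dd2 @ c)
        self.grads["centers"] += 2.0 * (
            dd2.sum(axis=(0, 1))[:, None] * c
            - np.einsum("bmk,bmd->kd", dd2, x)
        )
        return dx


class LSTM(Layer):
    """Masked unidirectional LSTM; returns per-step hidden states and the
    state at each sequence's true final position (masked carry-over)."""

    def __init__(self, din: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.din, self.hidden = din, hidden
        self.params["Wx"] = _glorot(rng, din, 4 * hidden, (din, 4 * hidden))
        self.params["Wh"] = _glorot(rng, hidden, 4 * hidden,
                                    (hidden, 4 * hidden))
        b = np.zeros(4 * hidden)
        b[hidden:2 * hidden] = 1.0      # forget-gate bias
        self.params["b"] = b
        self.zero_grads()

    def forward(self, x: np.ndarray, mask: np.ndarray):
        b, m, _ = x.shape
        hdim = self.hidden
        wx, wh, bias = self.params["Wx"], self.params["Wh"], self.params["b"]
        h = np.zeros((b, hdim))
        c = np.zeros((b, hdim))
        hs = np.zeros((b, m, hdim))
        steps = []
        xw = x @ wx
        for t in range(m):
            z = xw[:, t] + h @ wh + bias
            i = sigmoid(z[:, :hdim])
            f = sigmoid(z[:, hdim:2 * hdim])
            g = np.tanh(z[:, 2 * hdim:3 * hdim])
            o = sigmoid(z[:, 3 * hdim:])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            mt = mask[:, t:t + 1]
            steps.append((i, f, g, o, c, h, tc, mt))
            c = mt * c_new + (1.0 - mt) * c
            h = mt * h_new + (1.0 - mt) * h
            hs[:, t] = h
        self._cache = (x, steps)
        return hs, h

    def backward(self, dhs: Optional[np.ndarray], dh_final: np.ndarray):
        x, steps = self._cache
        b, m, _ = x.shape
        hdim = self.hidden
        wx, wh = self.params["Wx"], self.params["Wh"]
        dx = np.zeros_like(x)
        dh = dh_final.copy()
        dc = np.zeros((b, hdim))
        for t in reversed(range(m)):
            i, f, g, o, c_prev, h_prev, tc, mt = steps[t]
            dh_t = dh + (dhs[:, t] if dhs is not None else 0.0)
            dh_new = dh_t * mt
            dh_skip = dh_t * (1.0 - mt)
            dc_tot = dc * mt + dh_new * o * (1.0 - tc ** 2)
            dc_skip = dc * (1.0 - mt)
            do = dh_new * tc
            di = dc_tot * g
            dg = dc_tot * i
            df = dc_tot * c_prev
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f),
                 dg * (1 - g ** 2), do * o * (1 - o)], axis=1)
            self.grads["Wx"] += x[:, t].T @ dz
            self.grads["Wh"] += h_prev.T @ dz
            self.grads["b"] += dz.sum(axis=0)
            dx[:, t] = dz @ wx.T
            dh = dz @ wh.T + dh_skip
            dc = dc_tot * f + dc_skip
        return dx


class SimpleRNN(Layer):
    """Masked tanh RNN (the CNN+RNN ablation's recurrent unit)."""

    def __init__(self, din: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.din, self.hidden = din, hidden
        self.params["Wx"] = _glorot(rng, din, hidden, (din, hidden))
        self.params["Wh"] = _glorot(rng, hidden, hidden, (hidden, hidden))
        self.params["b"] = np.zeros(hidden)
        self.zero_grads()

    def forward(self, x: np.ndarray, mask: np.ndarray):
        b, m, _ = x.shape
        h = np.zeros((b, self.hidden))
        hs = np.zeros((b, m, self.hidden))
        steps = []
        xw = x @ self.params["Wx"]
        for t in range(m):
            a = np.tanh(xw[:, t] + h @ self.params["Wh"] + self.params["b"])
            mt = mask[:, t:t + 1]
            steps.append((h, a, mt))
            h = mt * a + (1.0 - mt) * h
            hs[:, t] = h
        self._cache = (x, steps)
        return hs, h

    def backward(self, dhs: Optional[np.ndarray], dh_final: np.ndarray):
        x, steps = self._cache
        dx = np.zeros_like(x)
        dh = dh_final.copy()
        for t in reversed(range(x.shape[1])):
            h_prev, a, mt = steps[t]
            dh_t = dh + (dhs[:, t] if dhs is not None else 0.0)
            da = dh_t * mt * (1.0 - a ** 2)
            self.grads["Wx"] += x[:, t].T @ da
            self.grads["Wh"] += h_prev.T @ da
            self.grads["b"] += da.sum(axis=0)
            dx[:, t] = da @ self.params["Wx"].T
            dh = da @ self.params["Wh"].T + dh_t * (1.0 - mt)
        return dx


def reverse_indices(lengths: np.ndarray, m: int) -> np.ndarray:
    """Per-row index map that reverses the valid prefix of each sequence."""
    t = np.arange(m)[None, :]
    lens = np.asarray(lengths)[:, None]
    return np.where(t < lens, lens - 1 - t, t)


def weighted_cross_entropy(logits: np.ndarray, labels: np.ndarray,
                           class_weights: np.ndarray):
    """Class-weighted softmax cross-entropy.

    Returns (mean weighted loss, gradient w.r.t. logits, probabilities).
    """
    p = softmax(logits, axis=-1)
    n = logits.shape[0]
    w = class_weights[labels]
    wsum = w.sum()
    logp = np.log(np.clip(p[np.arange(n), labels], 1e-300, None))
    loss = -(w * logp).sum() / wsum
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    dlogits *= (w / wsum)[:, None]
    return loss, dlogits, p


class Adam:
    """Adam over a list of layers (betas 0.9/0.999, eps 1e-8)."""

    def __init__(self, layers: Sequence[Layer], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.layers = list(layers)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in lay.params.items()}
                  for lay in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in lay.params.items()}
                  for lay in self.layers]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for lay, m, v in zip(self.layers, self.m, self.v):
            for k, p in lay.params.items():
                g = lay.grads[k]
                m[k] = b1 * m[k] + (1 - b1) * g
                v[k] = b2 * v[k] + (1 - b2) * g * g
                p -= self.lr * (m[k] / bc1) / (np.sqrt(v[k] / bc2) + self.eps)

    def zero_grads(self) -> None:
        for lay in self.layers:
            lay.zero_grads()
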