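"""Minimal seeded numpy neural-network layers for token sequence labeling.

Implements exactly what the keyword-selector architectures need — a
flattened dense layer, a per-timestep dense layer, an LSTM, and a 1-D
convolution, trained with Adam on masked binary cross-entropy — with fully
deterministic seeded initialization, shuffling and dropout.  Inputs are
(batch, length, features) arrays; outputs are per-position probabilities.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "sigmoid",
    "TimeDense",
    "FlatDense",
    "LSTMLayer",
    "Conv1D",
    "Dropout",
    "Concat",
    "Adam",
    "masked_bce_grad",
]


def sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30.0, 30.0)))


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class TimeDense(Layer):
    """Per-timestep affine map (B, L, Din) -> (B, L, Dout) with optional
    ReLU, shared across positions."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, relu: bool = False):
        self.W = rng.normal(0, np.sqrt(2.0 / d_in), (d_in, d_out))
        self.b = np.zeros(d_out)
        self.relu = relu
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        z = x @ self.W + self.b
        if self.relu:
            self._mask = z > 0
            z = z * self._mask
        return z

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self.relu:
            dy = dy * self._mask
        self.grads[0][...] = np.einsum("bli,blo->io", self._x, dy)
        self.grads[1][...] = dy.sum(axis=(0, 1))
        return dy @ self.W.T


class FlatDense(Layer):
    """Flattened affine map (B, L, Din) -> (B, L) — every output position
    sees the whole padded sequence (the 'dense' encoder)."""

    def __init__(self, length: int, d_in: int, rng: np.random.Generator):
        self.length = length
        self.W = rng.normal(0, 0.05, (length * d_in, length))
        self.b = np.zeros(length)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        self._xf = x.reshape(x.shape[0], -1)
        return self._xf @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._xf.T @ dy
        self.grads[1][...] = dy.sum(0)
        return (dy @ self.W.T).reshape(self._shape)


class LSTMLayer(Layer):
    """Unidirectional LSTM returning the hidden state at every timestep."""

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator):
        self.H = hidden
        s = np.sqrt(1.0 / max(d_in, hidden))
        self.Wx = rng.normal(0, s, (d_in, 4 * hidden))
        self.Wh = rng.normal(0, s, (hidden, 4 * hidden))
        self.b = np.zeros(4 * hidden)
        self.b[hidden : 2 * hidden] = 1.0  # forget-gate bias
        self.params = [self.Wx, self.Wh, self.b]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        B, L, _ = x.shape
        H = self.H
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        self._cache = []
        out = np.zeros((B, L, H))
        for t in range(L):
            z = x[:, t] @ self.Wx + h @ self.Wh + self.b
            i = sigmoid(z[:, :H])
            f = sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = sigmoid(z[:, 3 * H :])
            c_new = f * c + i * g
            tanc = np.tanh(c_new)
            self._cache.append((x[:, t], h, c, i, f, g, o, tanc))
            h = o * tanc
            c = c_new
            out[:, t] = h
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, L, H = dy.shape
        dx = np.zeros((B, L, self.Wx.shape[0]))
        for g in self.grads:
            g[...] = 0.0
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in range(L - 1, -1, -1):
            x_t, h_prev, c_prev, i, f, g, o, tanc = self._cache[t]
            dh = dy[:, t] + dh_next
            do = dh * tanc
            dc = dh * o * (1 - tanc**2) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g**2), do * o * (1 - o)],
                axis=1,
            )
            self.grads[0] += x_t.T @ dz
            self.grads[1] += h_prev.T @ dz
            self.grads[2] += dz.sum(0)
            dx[:, t] = dz @ self.Wx.T
            dh_next = dz @ self.Wh.T
            dc_next = dc * f
        return dx


class Conv1D(Layer):
    """Same-padded 1-D convolution over the sequence axis with ReLU."""

    def __init__(self, d_in: int, filters: int, kernel: int, rng: np.random.Generator):
        self.k = kernel
        self.W = rng.normal(0, np.sqrt(2.0 / (d_in * kernel)), (kernel, d_in, filters))
        self.b = np.zeros(filters)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def _pad(self, x: np.ndarray) -> np.ndarray:
        p = self.k // 2
        return np.pad(x, ((0, 0), (p, p), (0, 0)))

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        xp = self._pad(x)
        B, L, _ = x.shape
        z = np.zeros((B, L, self.W.shape[2]))
        for j in range(self.k):
            z += xp[:, j : j + L] @ self.W[j]
        z += self.b
        self._mask = z > 0
        return z * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = dy * self._mask
        xp = self._pad(self._x)
        B, L, _ = self._x.shape
        dxp = np.zeros_like(xp)
        for j in range(self.k):
            self.grads[0][j] = np.einsum("bli,blo->io", xp[:, j : j + L], dy)
            dxp[:, j : j + L] += dy @ self.W[j].T
        self.grads[1][...] = dy.sum(axis=(0, 1))
        p = self.k // 2
        return dxp[:, p : p + L]


class Dropout(Layer):
    """Inverted dropout with its own seeded stream (identity at predict)."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        return dy * self._mask


class Concat:
    """Concatenate two (B, L, *) feature blocks along the last axis."""

    def __init__(self, d_a: int):
        self.d_a = d_a

    def forward(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        return np.concatenate([a, b], axis=-1)

    def backward(self, dy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return dy[..., : self.d_a], dy[..., self.d_a :]


class Adam:
    def __init__(self, params: list[np.ndarray], grads: list[np.ndarray],
                 lr: float = 0.01, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params = params
        self.grads = grads
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mh = m / (1 - self.b1**self.t)
            vh = v / (1 - self.b2**self.t)
            p -= self.lr * mh / (np.sqrt(vh) + self.eps)


def masked_bce_grad(prob: np.ndarray, y: np.ndarray, mask: np.ndarray) -> tuple[float, np.ndarray]:
    """Masked binary cross-entropy loss and its gradient wrt the logits."""
    n = max(float(mask.sum()), 1.0)
    p = np.clip(prob, 1e-9, 1 - 1e-9)
    loss = float(-(mask * (y * np.log(p) + (1 - y) * np.log(1 - p))).sum() / n)
    return loss, (prob - y) * mask / n
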