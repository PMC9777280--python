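"""Minimal feed-forward / recurrent neural engine with manual backprop.

The survival networks in this package are small (tens of units, two time
steps), so the engine favours clarity over generality: each layer carries
its parameters and gradient buffers as plain numpy arrays, forward passes
cache what the backward pass needs, and optimisation is plain Adam.  All
randomness (weight init, dropout masks) flows through one
``numpy.random.Generator`` owned by the caller, which makes whole-training
runs bit-reproducible.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Dense", "ReLU", "BatchNorm", "Dropout", "Sequential",
           "ElmanRNN", "GRU", "Adam"]


class Layer:
    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def zero_grads(self) -> None:
        for g in self.grads():
            g[...] = 0.0

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _glorot(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-limit, limit, size=(n_in, n_out))


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = _glorot(rng, n_in, n_out)
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, train):
        self._x = x
        return x @ self.W + self.b

    def backward(self, gout):
        self.dW += self._x.T @ gout
        self.db += gout.sum(axis=0)
        return gout @ self.W.T


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, gout):
        return gout * self._mask


class BatchNorm(Layer):
    """Batch normalization with running statistics frozen at evaluation."""

    def __init__(self, dim: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(dim)
        self.beta = np.zeros(dim)
        self.dgamma = np.zeros(dim)
        self.dbeta = np.zeros(dim)
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]

    def forward(self, x, train):
        if train:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mu, var = self.running_mean, self.running_var
        self._inv_sd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv_sd
        self._train = train
        return self.gamma * self._xhat + self.beta

    def backward(self, gout):
        self.dgamma += (gout * self._xhat).sum(axis=0)
        self.dbeta += gout.sum(axis=0)
        if not self._train:
            return gout * self.gamma * self._inv_sd
        g = gout * self.gamma
        return self._inv_sd * (g - g.mean(axis=0)
                               - self._xhat * (g * self._xhat).mean(axis=0))


class Dropout(Layer):
    def __init__(self, p: float, rng: np.random.Generator):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must lie in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x, train):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.uniform(size=x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, gout):
        return gout if self._mask is None else gout * self._mask


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def grads(self):
        return [g for l in self.layers for g in l.grads()]

    def forward(self, x, train):
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, gout):
        for l in reversed(self.layers):
            gout = l.backward(gout)
        return gout


class ElmanRNN(Layer):
    """Simple tanh recurrent cell unrolled over a short sequence.

    Input shape (n, T, q); output is the final hidden state (n, hidden).
    """

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator):
        self.Wx = _glorot(rng, n_in, hidden)
        self.Wh = _glorot(rng, hidden, hidden)
        self.b = np.zeros(hidden)
        self.dWx = np.zeros_like(self.Wx)
        self.dWh = np.zeros_like(self.Wh)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.Wx, self.Wh, self.b]

    def grads(self):
        return [self.dWx, self.dWh, self.db]

    def forward(self, x, train):
        n, T, q = x.shape
        self._x = x
        self._hs = [np.zeros((n, self.b.size))]
        for t in range(T):
            a = x[:, t, :] @ self.Wx + self._hs[-1] @ self.Wh + self.b
            self._hs.append(np.tanh(a))
        return self._hs[-1]

    def backward(self, gout):
        x = self._x
        n, T, q = x.shape
        dx = np.zeros_like(x)
        dh = gout
        for t in range(T - 1, -1, -1):
            h_t, h_prev = self._hs[t + 1], self._hs[t]
            da = dh * (1.0 - h_t ** 2)
            self.dWx += x[:, t, :].T @ da
            self.dWh += h_prev.T @ da
            self.db += da.sum(axis=0)
            dx[:, t, :] = da @ self.Wx.T
            dh = da @ self.Wh.T
        return dx


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


class GRU(Layer):
    """Gated recurrent unit unrolled over a short sequence."""

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator):
        h = hidden
        self.Wz = _glorot(rng, n_in, h); self.Uz = _glorot(rng, h, h); self.bz = np.zeros(h)
        self.Wr = _glorot(rng, n_in, h); self.Ur = _glorot(rng, h, h); self.br = np.zeros(h)
        self.Wc = _glorot(rng, n_in, h); self.Uc = _glorot(rng, h, h); self.bc = np.zeros(h)
        self._p = [self.Wz, self.Uz, self.bz, self.Wr, self.Ur, self.br,
                   self.Wc, self.Uc, self.bc]
        self._g = [np.zeros_like(a) for a in self._p]

    def params(self):
        return self._p

    def grads(self):
        return self._g

    def forward(self, x, train):
        n, T, q = x.shape
        h = np.zeros((n, self.bz.size))
        self._x = x
        self._cache = []
        for t in range(T):
            xt = x[:, t, :]
            z = _sigmoid(xt @ self.Wz + h @ self.Uz + self.bz)
            r = _sigmoid(xt @ self.Wr + h @ self.Ur + self.br)
            c = np.tanh(xt @ self.Wc + (r * h) @ self.Uc + self.bc)
            h_new = (1.0 - z) * h + z * c
            self._cache.append((xt, h, z, r, c))
            h = h_new
        self._h_final = h
        return h

    def backward(self, gout):
        dWz, dUz, dbz, dWr, dUr, dbr, dWc, dUc, dbc = self._g
        dx = np.zeros_like(self._x)
        dh = gout
        for t in range(len(self._cache) - 1, -1, -1):
            xt, h_prev, z, r, c = self._cache[t]
            dz = dh * (c - h_prev) * z * (1.0 - z)
            dc = dh * z * (1.0 - c ** 2)
            dh_prev = dh * (1.0 - z)
            # candidate path
            dWc += xt.T @ dc
            dUc += (r * h_prev).T @ dc
            dbc += dc.sum(axis=0)
            drh = dc @ self.Uc.T
            dr = drh * h_prev * r * (1.0 - r)
            dh_prev += drh * r
            # gate paths
            dWz += xt.T @ dz
            dUz += h_prev.T @ dz
            dbz += dz.sum(axis=0)
            dh_prev += dz @ self.Uz.T
            dWr += xt.T @ dr
            dUr += h_prev.T @ dr
            dbr += dr.sum(axis=0)
            dh_prev += dr @ self.Ur.T
            dx[:, t, :] = dz @ self.Wz.T + dr @ self.Wr.T + dc @ self.Wc.T
            dh = dh_prev
        return dx


class Adam:
    """Adaptive-moment optimiser over a fixed parameter list."""

    def __init__(self, lr: float, params: list[np.ndarray],
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.params = params
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
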