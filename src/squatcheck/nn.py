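"""Minimal numpy neural-network layers for variable-length sequence classification.

Each layer consumes a single sequence shaped ``(T, C)`` (time by channels) or
a flat vector, and implements explicit backpropagation. Sequences of
different lengths are handled naturally by processing one sequence at a time
and averaging gradients over a minibatch — mathematically identical to
zero-padded batching with a length mask, without the masking bookkeeping.

Parameters live in per-layer dicts; :class:`Adam` updates them in place.
All randomness (initialization, dropout masks) flows through numpy
Generators, so training is bit-reproducible given a seed.
"""

from __future__ import annotations

import numpy as np


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = int(np.prod(shape[:-1])), int(shape[-1])
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, shape)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))


class Layer:
    """Base: parameters and matching gradient buffers keyed by name."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def zero_grad(self) -> None:
        for k, v in self.params.items():
            self.grads[k] = np.zeros_like(v)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    @property
    def n_params(self) -> int:
        return sum(v.size for v in self.params.values())


class Conv1D(Layer):
    """Temporal convolution, valid padding, stride 1, fused ReLU.

    Input ``(T, Cin)`` -> output ``(T-K+1, Cout)``: each output step mixes K
    consecutive frames across all input channels.
    """

    def __init__(self, kernel: int, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        self.kernel, self.c_in, self.c_out = kernel, c_in, c_out
        self.params = {
            "W": _glorot(rng, (kernel, c_in, c_out)),
            "b": np.zeros(c_out),
        }
        self.zero_grad()

    @property
    def min_length(self) -> int:
        return self.kernel

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        T = x.shape[0]
        T_out = T - self.kernel + 1
        if T_out < 1:
            raise ValueError(
                f"input length {T} shorter than kernel {self.kernel}"
            )
        W, b = self.params["W"], self.params["b"]
        z = np.zeros((T_out, self.c_out)) + b
        for k in range(self.kernel):
            z += x[k : k + T_out] @ W[k]
        self._x, self._mask = x, z > 0
        return np.where(self._mask, z, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dz = dy * self._mask
        x, W = self._x, self.params["W"]
        T_out = dz.shape[0]
        dx = np.zeros_like(x)
        for k in range(self.kernel):
            self.grads["W"][k] += x[k : k + T_out].T @ dz
            dx[k : k + T_out] += dz @ W[k].T
        self.grads["b"] += dz.sum(axis=0)
        return dx


class _LSTMDirection(Layer):
    """One direction of an LSTM; returns the final hidden state only."""

    def __init__(self, c_in: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.c_in, self.hidden = c_in, hidden
        self.params = {
            "Wx": _glorot(rng, (c_in, 4 * hidden)),
            "Wh": _glorot(rng, (hidden, 4 * hidden)),
            "b": np.zeros(4 * hidden),
        }
        # Forget-gate bias 1: keeps the cell state alive early in training.
        self.params["b"][hidden : 2 * hidden] = 1.0
        self.zero_grad()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        H = self.hidden
        Wx, Wh, b = self.params["Wx"], self.params["Wh"], self.params["b"]
        T = x.shape[0]
        h = np.zeros(H)
        c = np.zeros(H)
        cache = []
        xz = x @ Wx + b  # precompute input contributions for all steps
        for t in range(T):
            z = xz[t] + h @ Wh
            i, f = _sigmoid(z[:H]), _sigmoid(z[H : 2 * H])
            g, o = np.tanh(z[2 * H : 3 * H]), _sigmoid(z[3 * H :])
            c_prev, h_prev = c, h
            c = f * c + i * g
            tc = np.tanh(c)
            h = o * tc
            cache.append((i, f, g, o, c_prev, h_prev, tc))
        self._x, self._cache = x, cache
        return h

    def backward(self, dh_final: np.ndarray) -> np.ndarray:
        H = self.hidden
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        x, cache = self._x, self._cache
        T = x.shape[0]
        dx = np.zeros_like(x)
        dh = dh_final.copy()
        dc = np.zeros(H)
        for t in range(T - 1, -1, -1):
            i, f, g, o, c_prev, h_prev, tc = cache[t]
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc * tc)
            di, dg, df = dc * g, dc * i, dc * c_prev
            da = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g * g),
                    do * o * (1.0 - o),
                ]
            )
            self.grads["Wx"] += np.outer(x[t], da)
            self.grads["Wh"] += np.outer(h_prev, da)
            self.grads["b"] += da
            dx[t] = da @ Wx.T
            dh = da @ Wh.T
            dc = dc * f
        return dx


class BiLSTM(Layer):
    """Bidirectional LSTM summarized by the concatenated final hidden states.

    ``hidden`` is per direction; the output vector has ``2 * hidden``
    dimensions (so "64 outputs" means hidden=32 per direction).
    """

    def __init__(self, c_in: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.fwd = _LSTMDirection(c_in, hidden, rng)
        self.bwd = _LSTMDirection(c_in, hidden, rng)
        self.hidden = hidden

    @property
    def n_params(self) -> int:
        return self.fwd.n_params + self.bwd.n_params

    def zero_grad(self) -> None:
        self.fwd.zero_grad()
        self.bwd.zero_grad()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        hf = self.fwd.forward(x, train)
        hb = self.bwd.forward(x[::-1], train)
        return np.concatenate([hf, hb])

    def backward(self, dy: np.ndarray) -> np.ndarray:
        H = self.hidden
        dxf = self.fwd.backward(dy[:H])
        dxb = self.bwd.backward(dy[H:])
        return dxf + dxb[::-1]

    def iter_params(self):
        yield "fwd", self.fwd
        yield "bwd", self.bwd


class MeanPool(Layer):
    """Collapse time by averaging: ``(T, C)`` -> ``(C,)``."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._T = x.shape[0]
        return x.mean(axis=0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.tile(dy / self._T, (self._T, 1))


class Dense(Layer):
    def __init__(
        self, c_in: int, c_out: int, rng: np.random.Generator, relu: bool = True
    ):
        super().__init__()
        self.relu = relu
        self.params = {"W": _glorot(rng, (c_in, c_out)), "b": np.zeros(c_out)}
        self.zero_grad()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        z = x @ self.params["W"] + self.params["b"]
        self._x = x
        if self.relu:
            self._mask = z > 0
            return np.where(self._mask, z, 0.0)
        return z

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dz = dy * self._mask if self.relu else dy
        self.grads["W"] += np.outer(self._x, dz)
        self.grads["b"] += dz
        return dz @ self.params["W"].T


class Dropout(Layer):
    """Inverted dropout; identity at inference time."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not (0.0 <= rate < 1.0):
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max()
    e = np.exp(z)
    return e / e.sum()


def softmax_xent(logits: np.ndarray, label: int) -> tuple[float, np.ndarray]:
    """Cross-entropy loss and its gradient w.r.t. the logits."""
    p = softmax(logits)
    loss = -float(np.log(max(p[label], 1e-300)))
    dlogits = p.copy()
    dlogits[label] -= 1.0
    return loss, dlogits


class Adam:
    """Adam over a flat {path: array} parameter mapping, updating in place."""

    def __init__(
        self,
        lr: float = 0.003,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for key, p in params.items():
            g = grads[key]
            m = self.m.setdefault(key, np.zeros_like(p))
            v = self.v.setdefault(key, np.zeros_like(p))
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            m_hat = m / (1 - b1**self.t)
            v_hat = v / (1 - b2**self.t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
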