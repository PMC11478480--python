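"""Minimal recurrent neural-network core in NumPy.

Implements exactly what the two sequence models need: LSTM layers with
explicit backpropagation through time, bidirectional wrappers (full-sequence
or final-state output), inverted dropout, dense layers, softmax
cross-entropy and mean-squared-error losses, and Adam.  Gate order is
(input, forget, cell, output); forget-gate biases start at 1.  Kernels use
Glorot-uniform init and recurrent kernels are orthogonal per gate block.

Everything is float64 and deterministic given the construction/training
RNGs, which keeps gradients checkable against finite differences.
"""

from __future__ import annotations

import numpy as np


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def _orthogonal(rng: np.random.Generator, n: int) -> np.ndarray:
    a = rng.normal(size=(n, n))
    q, r = np.linalg.qr(a)
    return q * np.sign(np.diag(r))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Layer:
    """Base layer: parameter/gradient lists plus forward/backward."""

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x, train=False, rng=None):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - abstract
        raise NotImplementedError


class LSTM(Layer):
    """Unidirectional LSTM returning the full hidden sequence (B, T, H)."""

    def __init__(self, input_dim: int, hidden: int, rng: np.random.Generator):
        self.D, self.H = input_dim, hidden
        self.W = _glorot(rng, input_dim, 4 * hidden)
        self.U = np.concatenate([_orthogonal(rng, hidden) for _ in range(4)], axis=1)
        self.b = np.zeros(4 * hidden)
        self.b[hidden : 2 * hidden] = 1.0  # forget-gate bias
        self.dW = np.zeros_like(self.W)
        self.dU = np.zeros_like(self.U)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.U, self.b]

    def grads(self):
        return [self.dW, self.dU, self.db]

    def forward(self, x, train=False, rng=None):
        B, T, D = x.shape
        H = self.H
        zx = x.reshape(B * T, D) @ self.W
        zx = zx.reshape(B, T, 4 * H) + self.b
        i = np.empty((B, T, H)); f = np.empty((B, T, H))
        g = np.empty((B, T, H)); o = np.empty((B, T, H))
        c = np.empty((B, T, H)); h = np.empty((B, T, H))
        tc = np.empty((B, T, H))
        h_prev = np.zeros((B, H))
        c_prev = np.zeros((B, H))
        for t in range(T):
            z = zx[:, t] + h_prev @ self.U
            i[:, t] = _sigmoid(z[:, :H])
            f[:, t] = _sigmoid(z[:, H : 2 * H])
            g[:, t] = np.tanh(z[:, 2 * H : 3 * H])
            o[:, t] = _sigmoid(z[:, 3 * H :])
            c_prev = f[:, t] * c_prev + i[:, t] * g[:, t]
            c[:, t] = c_prev
            tc[:, t] = np.tanh(c_prev)
            h_prev = o[:, t] * tc[:, t]
            h[:, t] = h_prev
        self._cache = (x, i, f, g, o, c, tc, h)
        return h

    def backward(self, dh_seq):
        x, i, f, g, o, c, tc, h = self._cache
        B, T, D = x.shape
        H = self.H
        dz_seq = np.empty((B, T, 4 * H))
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        Ut = self.U.T
        for t in range(T - 1, -1, -1):
            dh = dh_seq[:, t] + dh_next
            it, ft, gt, ot, tct = i[:, t], f[:, t], g[:, t], o[:, t], tc[:, t]
            dc = dc_next + dh * ot * (1.0 - tct * tct)
            c_prev = c[:, t - 1] if t > 0 else 0.0
            dz = np.empty((B, 4 * H))
            dz[:, :H] = dc * gt * it * (1.0 - it)
            dz[:, H : 2 * H] = dc * c_prev * ft * (1.0 - ft)
            dz[:, 2 * H : 3 * H] = dc * it * (1.0 - gt * gt)
            dz[:, 3 * H :] = dh * tct * ot * (1.0 - ot)
            dz_seq[:, t] = dz
            dh_next = dz @ Ut
            dc_next = dc * f[:, t]
        dz_flat = dz_seq.reshape(B * T, 4 * H)
        h_prev_seq = np.concatenate(
            [np.zeros((B, 1, H)), h[:, :-1]], axis=1
        ).reshape(B * T, H)
        self.dW[...] = x.reshape(B * T, D).T @ dz_flat
        self.dU[...] = h_prev_seq.T @ dz_flat
        self.db[...] = dz_flat.sum(axis=0)
        dx = (dz_flat @ self.W.T).reshape(B, T, D)
        return dx


class BiLSTM(Layer):
    """Bidirectional LSTM: forward + time-reversed pass, concatenated.

    With ``return_sequences`` the output is (B, T, 2H); otherwise the final
    states of both directions are concatenated into (B, 2H) — the backward
    direction's final state summarises the sequence read from the end.
    """

    def __init__(
        self,
        input_dim: int,
        hidden: int,
        rng: np.random.Generator,
        return_sequences: bool = True,
    ):
        self.fwd = LSTM(input_dim, hidden, rng)
        self.bwd = LSTM(input_dim, hidden, rng)
        self.H = hidden
        self.return_sequences = return_sequences

    @property
    def output_dim(self) -> int:
        return 2 * self.H

    def params(self):
        return self.fwd.params() + self.bwd.params()

    def grads(self):
        return self.fwd.grads() + self.bwd.grads()

    def forward(self, x, train=False, rng=None):
        hf = self.fwd.forward(x)
        hb_rev = self.bwd.forward(x[:, ::-1])
        self._shape = x.shape
        if self.return_sequences:
            return np.concatenate([hf, hb_rev[:, ::-1]], axis=2)
        return np.concatenate([hf[:, -1], hb_rev[:, -1]], axis=1)

    def backward(self, dout):
        B, T, _ = self._shape
        H = self.H
        if self.return_sequences:
            dhf = dout[:, :, :H]
            dhb = dout[:, ::-1, H:]
        else:
            dhf = np.zeros((B, T, H))
            dhf[:, -1] = dout[:, :H]
            dhb = np.zeros((B, T, H))
            dhb[:, -1] = dout[:, H:]
        dx = self.fwd.backward(np.ascontiguousarray(dhf))
        dx_rev = self.bwd.backward(np.ascontiguousarray(dhb))
        return dx + dx_rev[:, ::-1]


class Dropout(Layer):
    """Inverted dropout; identity at inference time."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an RNG")
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Dense(Layer):
    """Affine layer on (B, D) inputs with optional relu/tanh activation."""

    def __init__(
        self,
        input_dim: int,
        units: int,
        rng: np.random.Generator,
        activation: str | None = None,
    ):
        if activation not in (None, "relu", "tanh"):
            raise ValueError(f"unsupported activation {activation!r}")
        self.W = _glorot(rng, input_dim, units)
        self.b = np.zeros(units)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.activation = activation

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, train=False, rng=None):
        z = x @ self.W + self.b
        if self.activation == "relu":
            out = np.maximum(z, 0.0)
        elif self.activation == "tanh":
            out = np.tanh(z)
        else:
            out = z
        self._cache = (x, out)
        return out

    def backward(self, dout):
        x, out = self._cache
        if self.activation == "relu":
            dz = dout * (out > 0)
        elif self.activation == "tanh":
            dz = dout * (1.0 - out * out)
        else:
            dz = dout
        self.dW[...] = x.T @ dz
        self.db[...] = dz.sum(axis=0)
        return dz @ self.W.T


class Network:
    """A plain layer stack with shared parameter plumbing."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, train: bool = False, rng: np.random.Generator | None = None):
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads()]

    def n_params(self) -> int:
        return sum(p.size for p in self.params())

    def get_state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params()]

    def set_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.params(), state, strict=True):
            p[...] = s


class Adam:
    """Adam optimiser updating parameters in place."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v, strict=True):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_xent(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy over integer labels, with gradient."""
    B = logits.shape[0]
    p = softmax(logits)
    loss = -np.mean(np.log(p[np.arange(B), labels] + 1e-300))
    dlogits = p.copy()
    dlogits[np.arange(B), labels] -= 1.0
    return float(loss), dlogits / B


def mse(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error over all elements, with gradient."""
    diff = pred - target
    loss = float(np.mean(diff * diff))
    return loss, 2.0 * diff / diff.size
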