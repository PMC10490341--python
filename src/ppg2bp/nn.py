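"""Minimal numpy recurrent network: stacked (Bi)LSTM + dense regressor.

Implements exactly what the blood-pressure model needs — a bidirectional
first LSTM layer, further unidirectional LSTM layers, and a linear head read
from the final timestep — with manual backpropagation through time, Adam,
gradient clipping and fully seeded initialization.  Small by design: batch
inputs are (batch, time, features) float64 arrays and the whole state lives
in plain ndarrays, which keeps runs bit-reproducible on CPU.
"""

from __future__ import annotations

import numpy as np

from .errors import TrainingError


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=(fan_in, fan_out))


class _LSTMDirection:
    """One direction of an LSTM layer (gate order i, f, g, o)."""

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator):
        self.in_dim, self.hidden = in_dim, hidden
        self.Wx = _glorot(rng, in_dim, 4 * hidden)
        self.Wh = _glorot(rng, hidden, 4 * hidden)
        self.b = np.zeros(4 * hidden)
        self.b[hidden : 2 * hidden] = 1.0  # forget-gate bias

    def params(self):
        return [self.Wx, self.Wh, self.b]

    def forward(self, X: np.ndarray) -> np.ndarray:
        B, T, _ = X.shape
        H = self.hidden
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        self._cache = []
        out = np.empty((B, T, H))
        for t in range(T):
            a = X[:, t] @ self.Wx + h @ self.Wh + self.b
            i = _sigmoid(a[:, :H])
            f = _sigmoid(a[:, H : 2 * H])
            g = np.tanh(a[:, 2 * H : 3 * H])
            o = _sigmoid(a[:, 3 * H :])
            c_prev = c
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h = o * tc
            out[:, t] = h
            self._cache.append((X[:, t], i, f, g, o, c_prev, tc))
        return out

    def backward(self, dOut: np.ndarray, h_all: np.ndarray) -> np.ndarray:
        B, T, H = dOut.shape
        dWx = np.zeros_like(self.Wx)
        dWh = np.zeros_like(self.Wh)
        db = np.zeros_like(self.b)
        dX = np.empty((B, T, self.in_dim))
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            x_t, i, f, g, o, c_prev, tc = self._cache[t]
            h_prev = h_all[:, t - 1] if t > 0 else np.zeros((B, H))
            dh = dOut[:, t] + dh_next
            do = dh * tc
            dc = dh * o * (1 - tc**2) + dc_next
            di, dg, df = dc * g, dc * i, dc * c_prev
            da = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g**2),
                 do * o * (1 - o)],
                axis=1,
            )
            dWx += x_t.T @ da
            dWh += h_prev.T @ da
            db += da.sum(axis=0)
            dX[:, t] = da @ self.Wx.T
            dh_next = da @ self.Wh.T
            dc_next = dc * f
        self.grads = [dWx, dWh, db]
        return dX


class LSTMLayer:
    """(Bi)directional LSTM layer returning the full output sequence."""

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator,
                 bidirectional: bool = False):
        self.bidirectional = bidirectional
        self.fwd = _LSTMDirection(in_dim, hidden, rng)
        self.bwd = _LSTMDirection(in_dim, hidden, rng) if bidirectional else None
        self.out_dim = hidden * (2 if bidirectional else 1)

    def params(self):
        p = self.fwd.params()
        return p + self.bwd.params() if self.bwd else p

    def grads(self):
        g = self.fwd.grads
        return g + self.bwd.grads if self.bwd else g

    def forward(self, X: np.ndarray) -> np.ndarray:
        self._hf = self.fwd.forward(X)
        if not self.bidirectional:
            return self._hf
        self._hb = self.bwd.forward(X[:, ::-1])
        return np.concatenate([self._hf, self._hb[:, ::-1]], axis=2)

    def backward(self, dOut: np.ndarray) -> np.ndarray:
        if not self.bidirectional:
            return self.fwd.backward(dOut, self._hf)
        H = self.fwd.hidden
        dX = self.fwd.backward(dOut[:, :, :H], self._hf)
        dX += self.bwd.backward(dOut[:, ::-1, H:], self._hb)[:, ::-1]
        return dX


class DenseHead:
    """Linear map from the final-timestep hidden state to one output."""

    def __init__(self, in_dim: int, rng: np.random.Generator):
        self.W = _glorot(rng, in_dim, 1)
        self.b = np.zeros(1)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return self._grads

    def forward(self, h_last: np.ndarray) -> np.ndarray:
        self._h = h_last
        return (h_last @ self.W + self.b).ravel()

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = dy[:, None]
        self._grads = [self._h.T @ dy, dy.sum(axis=0)]
        return dy @ self.W.T


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g**2
            mh = m / (1 - self.b1**self.t)
            vh = v / (1 - self.b2**self.t)
            p -= self.lr * mh / (np.sqrt(vh) + self.eps)


class SequenceRegressor:
    """BiLSTM -> stacked LSTM -> dense scalar regressor (MSE loss, Adam)."""

    def __init__(self, in_dim: int, bilstm_units: int, lstm_units: tuple[int, ...],
                 seed: int = 0):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 1337]))
        self.layers: list[LSTMLayer] = []
        dim = in_dim
        self.layers.append(LSTMLayer(dim, bilstm_units, rng, bidirectional=True))
        dim = self.layers[-1].out_dim
        for u in lstm_units:
            self.layers.append(LSTMLayer(dim, u, rng))
            dim = u
        self.head = DenseHead(dim, rng)
        self.in_dim = in_dim

    # -- parameter plumbing -------------------------------------------------
    def params(self) -> list[np.ndarray]:
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        out.extend(self.head.params())
        return out

    def grads(self) -> list[np.ndarray]:
        out = []
        for layer in self.layers:
            out.extend(layer.grads())
        out.extend(self.head.grads())
        return out

    def get_state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params()]

    def set_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.params(), state):
            p[...] = s

    # -- forward / backward -------------------------------------------------
    def forward(self, X: np.ndarray) -> np.ndarray:
        if X.ndim != 3 or X.shape[2] != self.in_dim:
            raise TrainingError(
                f"input schema mismatch: got {X.shape}, expected (*, *, {self.in_dim})"
            )
        h = X
        for layer in self.layers:
            h = layer.forward(h)
        self._T = h.shape[1]
        return self.head.forward(h[:, -1])

    def backward(self, dy: np.ndarray) -> None:
        dh_last = self.head.backward(dy)
        B = dh_last.shape[0]
        for j, layer in enumerate(reversed(self.layers)):
            if j == 0:
                dH = np.zeros((B, self._T, layer.out_dim))
                dH[:, -1] = dh_last
            dH = layer.backward(dH)

    def train_batch(self, X: np.ndarray, y: np.ndarray, opt: Adam,
                    clip_norm: float = 5.0) -> float:
        pred = self.forward(X)
        err = pred - y
        loss = float(np.mean(err**2))
        if not np.isfinite(loss):
            raise TrainingError(f"divergent loss: {loss}")
        self.backward(2.0 * err / len(y))
        grads = self.grads()
        norm = np.sqrt(sum(float((g**2).sum()) for g in grads))
        if norm > clip_norm:
            grads = [g * (clip_norm / norm) for g in grads]
        opt.step(grads)
        return loss

    def predict(self, X: np.ndarray, batch_size: int = 512) -> np.ndarray:
        out = [self.forward(X[i : i + batch_size])
               for i in range(0, len(X), batch_size)]
        return np.concatenate(out) if out else np.empty(0)
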