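"""LSTM and bidirectional wrapper with full backpropagation through time."""

from __future__ import annotations

import numpy as np

from .layers import Layer, glorot

__all__ = ["LSTM", "Bidirectional"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -40, 40)))


class LSTM(Layer):
    """Single LSTM layer over (N, T, D).

    Returns the final hidden state (N, H), or the full state sequence
    (N, T, H) with ``return_sequences`` (needed when stacking a second
    recurrent layer).  ``reverse=True`` processes time back-to-front — the
    backward half of a bidirectional stack.  The forget-gate bias starts at
    1 (standard trick to keep early memory open).
    """

    def __init__(
        self,
        in_dim: int,
        units: int,
        rng: np.random.Generator,
        return_sequences: bool = False,
        reverse: bool = False,
    ):
        h = units
        self.wx = glorot(rng, (in_dim, 4 * h), in_dim, 4 * h)
        self.wh = glorot(rng, (h, 4 * h), h, 4 * h)
        self.b = np.zeros(4 * h)
        self.b[h : 2 * h] = 1.0  # forget-gate bias
        self.gwx = np.zeros_like(self.wx)
        self.gwh = np.zeros_like(self.wh)
        self.gb = np.zeros_like(self.b)
        self.units = h
        self.return_sequences = return_sequences
        self.reverse = reverse

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.reverse:
            x = x[:, ::-1, :]
        n, t, _ = x.shape
        h = self.units
        self._x = x
        self._cache = []
        h_t = np.zeros((n, h))
        c_t = np.zeros((n, h))
        hs = np.empty((n, t, h))
        for step in range(t):
            z = x[:, step, :] @ self.wx + h_t @ self.wh + self.b
            i = _sigmoid(z[:, :h])
            f = _sigmoid(z[:, h : 2 * h])
            g = np.tanh(z[:, 2 * h : 3 * h])
            o = _sigmoid(z[:, 3 * h :])
            c_new = f * c_t + i * g
            tc = np.tanh(c_new)
            self._cache.append((h_t, c_t, i, f, g, o, tc))
            c_t = c_new
            h_t = o * tc
            hs[:, step, :] = h_t
        self._hs = hs
        if self.return_sequences:
            return hs[:, ::-1, :] if self.reverse else hs
        return h_t

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, t, d = self._x.shape
        h = self.units
        if self.return_sequences:
            gseq = grad[:, ::-1, :] if self.reverse else grad
        else:
            gseq = None
        self.gwx[:] = 0.0
        self.gwh[:] = 0.0
        self.gb[:] = 0.0
        gx = np.zeros_like(self._x)
        dh = np.zeros((n, h)) if gseq is not None else grad.copy()
        dc = np.zeros((n, h))
        for step in range(t - 1, -1, -1):
            if gseq is not None:
                dh = dh + gseq[:, step, :]
            h_prev, c_prev, i, f, g, o, tc = self._cache[step]
            do = dh * tc
            dct = dc + dh * o * (1.0 - tc * tc)
            di = dct * g
            df = dct * c_prev
            dg = dct * i
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1.0 - g * g), do * o * (1 - o)], axis=1
            )
            self.gwx += self._x[:, step, :].T @ dz
            self.gwh += h_prev.T @ dz
            self.gb += dz.sum(axis=0)
            gx[:, step, :] = dz @ self.wx.T
            dh = dz @ self.wh.T
            dc = dct * f
        return gx[:, ::-1, :] if self.reverse else gx

    def params(self):
        return [(self.wx, self.gwx), (self.wh, self.gwh), (self.b, self.gb)]


class Bidirectional(Layer):
    """Concatenate a forward and a backward LSTM over the same input."""

    def __init__(
        self,
        in_dim: int,
        units: int,
        rng: np.random.Generator,
        return_sequences: bool = False,
    ):
        self.fwd = LSTM(in_dim, units, rng, return_sequences=return_sequences)
        self.bwd = LSTM(in_dim, units, rng, return_sequences=return_sequences, reverse=True)
        self.units = units
        self.return_sequences = return_sequences

    def forward(self, x: np.ndarray) -> np.ndarray:
        return np.concatenate([self.fwd.forward(x), self.bwd.forward(x)], axis=-1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        h = self.units
        return self.fwd.backward(grad[..., :h]) + self.bwd.backward(grad[..., h:])

    def params(self):
        return self.fwd.params() + self.bwd.params()
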