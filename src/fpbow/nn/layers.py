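"""Feed-forward layers with manual backprop.

Convention: ``forward(x)`` caches what ``backward(grad)`` needs;
``backward`` returns the gradient w.r.t. the layer input and fills the
layer's parameter gradients.  ``params()`` yields (value, grad) array
pairs that the optimizer updates in place.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Layer", "Embedding", "Conv1D", "ReLU", "MaxPool1D", "Flatten", "Dense"]


def glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def params(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return []

    @property
    def n_params(self) -> int:
        return sum(int(np.prod(p.shape)) for p, _ in self.params())


class Embedding(Layer):
    """Integer codes (N, L) → dense vectors (N, L, dim); index 0 is a frozen pad."""

    def __init__(self, vocab_size: int, dim: int, rng: np.random.Generator):
        self.w = rng.uniform(-0.05, 0.05, size=(vocab_size, dim))
        self.w[0] = 0.0
        self.gw = np.zeros_like(self.w)
        self.vocab_size = vocab_size
        self.dim = dim

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.min() < 0 or x.max() >= self.vocab_size:
            raise ValueError(f"token codes out of range [0, {self.vocab_size})")
        self._x = x
        return self.w[x]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.gw[:] = 0.0
        np.add.at(self.gw, self._x, grad)
        self.gw[0] = 0.0  # pad row stays zero
        return np.zeros(self._x.shape)  # integer input: no upstream gradient

    def params(self):
        return [(self.w, self.gw)]


class Conv1D(Layer):
    """Valid 1-D convolution over (N, L, C_in) → (N, L − k + 1, C_out)."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int, rng: np.random.Generator):
        fan_in = kernel_size * in_channels
        self.w = glorot(rng, (fan_in, out_channels), fan_in, out_channels)
        self.b = np.zeros(out_channels)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self.k = kernel_size
        self.in_channels = in_channels
        self.out_channels = out_channels

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, length, c = x.shape
        if length < self.k:
            raise ValueError(f"sequence length {length} shorter than kernel {self.k}")
        # (N, L', C, k) -> (N, L', k*C) columns
        win = np.lib.stride_tricks.sliding_window_view(x, self.k, axis=1)
        cols = win.transpose(0, 1, 3, 2).reshape(n, length - self.k + 1, self.k * c)
        self._cols, self._in_shape = cols, x.shape
        return cols @ self.w + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, lp, _ = grad.shape
        cols2 = self._cols.reshape(-1, self.k * self.in_channels)
        self.gw[:] = cols2.T @ grad.reshape(-1, self.out_channels)
        self.gb[:] = grad.sum(axis=(0, 1))
        wk = self.w.reshape(self.k, self.in_channels, self.out_channels)
        gx = np.zeros(self._in_shape)
        for i in range(self.k):
            gx[:, i : i + lp, :] += grad @ wk[i].T
        return gx

    def params(self):
        return [(self.w, self.gw), (self.b, self.gb)]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class MaxPool1D(Layer):
    """Non-overlapping max pooling along time; a trailing remainder is dropped."""

    def __init__(self, pool_size: int):
        self.p = pool_size

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, length, c = x.shape
        chunks = length // self.p
        if chunks == 0:
            raise ValueError(f"sequence length {length} shorter than pool size {self.p}")
        xt = x[:, : chunks * self.p, :].reshape(n, chunks, self.p, c)
        self._arg = xt.argmax(axis=2)
        self._in_shape = x.shape
        return xt.max(axis=2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, chunks, c = grad.shape
        gx = np.zeros(self._in_shape)
        gt = gx[:, : chunks * self.p, :].reshape(n, chunks, self.p, c)
        ni, ci, cc = np.ogrid[:n, :chunks, :c]
        gt[ni, ci, self._arg, cc] = grad
        return gx

    def params(self):
        return []


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.w = glorot(rng, (in_dim, out_dim), in_dim, out_dim)
        self.b = np.zeros(out_dim)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.gw[:] = self._x.T @ grad
        self.gb[:] = grad.sum(axis=0)
        return grad @ self.w.T

    def params(self):
        return [(self.w, self.gw), (self.b, self.gb)]
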