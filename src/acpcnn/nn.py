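"""Minimal seeded numpy neural-network layers and the Adam optimizer.

Implements exactly the pieces the multi-headed classifier needs: 1-D valid
convolution (stride 1) over sequence rows with the representation columns as
input channels, ReLU, inverted dropout, dense layers, softmax cross-entropy,
an L2 penalty on weights, and Adam.  All randomness (initialization and
dropout masks) flows through a single ``numpy.random.Generator``, so a fixed
seed reproduces training bitwise on the same platform.
"""

from __future__ import annotations

import numpy as np


class Layer:
    """Forward/backward layer with trainable parameters in ``params``."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def l2_params(self) -> list[int]:
        """Indices into ``params`` that the L2 penalty applies to (weights only)."""
        return []

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params))


class Conv1D(Layer):
    """Stride-1 valid 1-D convolution: (B, L, C_in) -> (B, L-kernel+1, filters).

    He-normal initialization (appropriate for the ReLU that follows).
    """

    def __init__(self, in_channels: int, filters: int, kernel: int, rng) -> None:
        super().__init__()
        if kernel < 1:
            raise ValueError("kernel must be >= 1")
        self.in_channels = in_channels
        self.filters = filters
        self.kernel = kernel
        std = np.sqrt(2.0 / (kernel * in_channels))
        w = rng.normal(0.0, std, size=(kernel * in_channels, filters))
        b = np.zeros(filters)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]

    def l2_params(self) -> list[int]:
        return [0]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        B, L, C = x.shape
        if C != self.in_channels:
            raise ValueError(f"expected {self.in_channels} channels, got {C}")
        if L < self.kernel:
            raise ValueError(f"input length {L} shorter than kernel {self.kernel}")
        # (B, L_out, kernel, C) windows -> im2col matmul
        win = np.lib.stride_tricks.sliding_window_view(x, self.kernel, axis=1)
        # sliding_window_view gives (B, L_out, C, kernel); reorder to (.., kernel, C)
        win = win.transpose(0, 1, 3, 2)
        self._cols = win.reshape(B, -1, self.kernel * self.in_channels)
        w, b = self.params
        return self._cols @ w + b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        w, _ = self.params
        B, L_out, _ = dout.shape
        cols = self._cols.reshape(-1, self.kernel * self.in_channels)
        dflat = dout.reshape(-1, self.filters)
        self.grads[0][...] = cols.T @ dflat
        self.grads[1][...] = dflat.sum(axis=0)
        dcols = (dout @ w.T).reshape(B, L_out, self.kernel, self.in_channels)
        L = L_out + self.kernel - 1
        dx = np.zeros((B, L, self.in_channels))
        for i in range(self.kernel):  # col2im scatter-add; kernel is tiny
            dx[:, i : i + L_out, :] += dcols[:, :, i, :]
        return dx


class Dense(Layer):
    """Fully connected layer: (B, n_in) -> (B, units)."""

    def __init__(self, n_in: int, units: int, rng) -> None:
        super().__init__()
        std = np.sqrt(2.0 / n_in)
        w = rng.normal(0.0, std, size=(n_in, units))
        b = np.zeros(units)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]

    def l2_params(self) -> list[int]:
        return [0]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        w, b = self.params
        return x @ w + b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        w, _ = self.params
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ w.T


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class Dropout(Layer):
    """Inverted dropout: active only in training, identity at inference."""

    def __init__(self, rate: float, rng) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate {rate} outside [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        return dout * self._mask


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    """Mean negative log-likelihood of integer labels ``y``."""
    eps = 1e-12
    return float(-np.mean(np.log(probs[np.arange(len(y)), y] + eps)))


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(
        self,
        params: list[np.ndarray],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            m_hat = m / (1 - b1**self.t)
            v_hat = v / (1 - b2**self.t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
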