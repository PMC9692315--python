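"""Minimal NumPy layers, losses and Adam optimizer for the hybrid classifier.

Everything runs in float64 on the CPU; forward passes cache what the
matching backward pass needs.  Shapes follow the sequence convention
``(batch, length, channels)`` for 1-D convolution inputs and
``(batch, features)`` for dense inputs.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer", "Conv1D", "MaxPool1D", "Flatten", "Dense", "ReLU", "Dropout",
    "Branch", "Adam", "sigmoid", "softmax",
    "binary_cross_entropy", "categorical_cross_entropy",
]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def binary_cross_entropy(p: np.ndarray, y: np.ndarray, eps: float = 1e-12) -> float:
    p = np.clip(p.ravel(), eps, 1 - eps)
    y = y.ravel()
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def categorical_cross_entropy(p: np.ndarray, y_onehot: np.ndarray,
                              eps: float = 1e-12) -> float:
    return float(-np.mean(np.sum(y_onehot * np.log(np.clip(p, eps, 1.0)), axis=1)))


class Layer:
    """Base layer: parameters and their gradients are parallel lists."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1D(Layer):
    """Valid-mode 1-D convolution: (n, L, c_in) -> (n, L-k+1, f)."""

    def __init__(self, c_in: int, n_filters: int, kernel: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        if kernel < 1 or n_filters < 1:
            raise ValueError("kernel and n_filters must be positive")
        self.kernel = kernel
        # He initialization for ReLU nonlinearities
        std = np.sqrt(2.0 / (kernel * c_in))
        self.W = rng.normal(0.0, std, size=(kernel, c_in, n_filters))
        self.b = np.zeros(n_filters)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        L_out = x.shape[1] - self.kernel + 1
        if L_out < 1:
            raise ValueError(
                f"input length {x.shape[1]} shorter than kernel {self.kernel}"
            )
        self._x = x
        out = np.broadcast_to(self.b, (x.shape[0], L_out, self.b.size)).copy()
        for i in range(self.kernel):
            out += x[:, i:i + L_out, :] @ self.W[i]
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x = self._x
        L_out = grad.shape[1]
        dx = np.zeros_like(x)
        for i in range(self.kernel):
            self.grads[0][i] = np.einsum("nlc,nlf->cf", x[:, i:i + L_out, :], grad)
            dx[:, i:i + L_out, :] += grad @ self.W[i].T
        self.grads[1][...] = grad.sum(axis=(0, 1))
        return dx


class MaxPool1D(Layer):
    """Non-overlapping max pooling along the length axis (stride = pool)."""

    def __init__(self, pool: int) -> None:
        super().__init__()
        if pool < 1:
            raise ValueError("pool length must be positive")
        self.pool = pool

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, L, f = x.shape
        L_out = L // self.pool
        if L_out < 1:
            raise ValueError(f"length {L} shorter than pool {self.pool}")
        x = x[:, : L_out * self.pool, :]
        windows = x.reshape(n, L_out, self.pool, f)
        self._argmax = windows.argmax(axis=2)
        self._in_shape = (n, L, f)
        return windows.max(axis=2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, L, f = self._in_shape
        L_out = grad.shape[1]
        dx = np.zeros((n, L_out, self.pool, f))
        n_idx, l_idx, f_idx = np.ogrid[:n, :L_out, :f]
        dx[n_idx, l_idx, self._argmax, f_idx] = grad
        out = np.zeros((n, L, f))
        out[:, : L_out * self.pool, :] = dx.reshape(n, L_out * self.pool, f)
        return out


class Flatten(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        std = np.sqrt(2.0 / d_in)
        self.W = rng.normal(0.0, std, size=(d_in, d_out))
        self.b = np.zeros(d_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ grad
        self.grads[1][...] = grad.sum(axis=0)
        return grad @ self.W.T


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class Dropout(Layer):
    """Inverted dropout; identity at inference time."""

    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad if self._mask is None else grad * self._mask


class Branch:
    """A layer stack applied to one input of the multi-branch network."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]


class Adam:
    """Adaptive-moment gradient descent over a flat parameter list."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            m_hat = m / (1 - b1 ** self.t)
            v_hat = v / (1 - b2 ** self.t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
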