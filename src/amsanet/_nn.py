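"""A compact NumPy neural-network engine for 1-D convolutional regression.

Implements exactly the layer set the AMSA regressor needs — 1-D "same"
convolution (im2col + BLAS matmul), batch normalisation, leaky ReLU,
stride-2 max pooling (ceil mode), global max pooling, inverted dropout and
dense layers — together with reverse-mode gradients, an Adam optimizer and
an MSE training loop.  Arrays are (batch, channels, length) float32 by
default; float64 inputs propagate for gradient checking.

Every source of randomness (init, shuffling, dropout) comes from a
single ``numpy.random.Generator``, so training is bit-deterministic for a
fixed seed on a given BLAS.
"""

from __future__ import annotations

import numpy as np


class Layer:
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """(parameter, gradient) pairs; empty for stateless layers."""
        return []


class Conv1d(Layer):
    """Stride-1 'same' 1-D convolution (cross-correlation), odd kernel width."""

    def __init__(self, c_in: int, c_out: int, width: int,
                 rng: np.random.Generator, dtype=np.float32) -> None:
        assert width % 2 == 1
        fan_in, fan_out = c_in * width, c_out * width
        std = np.sqrt(2.0 / (fan_in + fan_out))  # Xavier normal
        self.w = rng.normal(0.0, std, size=(c_out, c_in, width)).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self.width = width

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        bsz, c_in, length = x.shape
        pad = self.width // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
        # time-major layout: one BLAS matmul per kernel tap, no im2col copy
        xt = np.ascontiguousarray(xp.transpose(0, 2, 1))  # (B, L+2p, Cin)
        out = np.empty((bsz, length, self.w.shape[0]), dtype=x.dtype)
        out[...] = self.b
        for j in range(self.width):
            out += xt[:, j:j + length, :] @ self.w[:, :, j].T
        self._xt, self._xshape = xt, x.shape
        return out.transpose(0, 2, 1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        bsz, c_in, length = self._xshape
        pad = self.width // 2
        gt = np.ascontiguousarray(grad.transpose(0, 2, 1))  # (B, L, Cout)
        g2 = gt.reshape(bsz * length, -1)
        self.db[...] = g2.sum(axis=0)
        dxt = np.zeros((bsz, length + 2 * pad, c_in), dtype=grad.dtype)
        for j in range(self.width):
            self.dw[:, :, j] = g2.T @ self._xt[:, j:j + length, :].reshape(
                bsz * length, c_in)
            dxt[:, j:j + length, :] += gt @ self.w[:, :, j]
        self._xt = None
        return dxt[:, pad:pad + length, :].transpose(0, 2, 1)

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]


class BatchNorm1d(Layer):
    """Per-channel batch normalisation over (batch, length)."""

    def __init__(self, channels: int, momentum: float = 0.1,
                 eps: float = 1e-5, dtype=np.float32) -> None:
        self.gamma = np.ones(channels, dtype=dtype)
        self.beta = np.zeros(channels, dtype=dtype)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.run_mean = np.zeros(channels, dtype=dtype)
        self.run_var = np.ones(channels, dtype=dtype)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.run_mean += self.momentum * (mean - self.run_mean)
            self.run_var += self.momentum * (var - self.run_var)
        else:
            mean, var = self.run_mean, self.run_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[:, None]) * inv[:, None]
        self._xhat, self._inv, self._m = xhat, inv, x.shape[0] * x.shape[2]
        return self.gamma[:, None] * xhat + self.beta[:, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv, m = self._xhat, self._inv, self._m
        self.dgamma[...] = (grad * xhat).sum(axis=(0, 2))
        self.dbeta[...] = grad.sum(axis=(0, 2))
        gxh = grad * self.gamma[:, None]
        dx = (inv[:, None] / m) * (
            m * gxh
            - gxh.sum(axis=(0, 2), keepdims=True)
            - xhat * (gxh * xhat).sum(axis=(0, 2), keepdims=True)
        )
        self._xhat = None
        return dx

    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.01) -> None:
        self.slope = slope

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._neg = x < 0
        return np.maximum(x, np.float32(self.slope) * x) if x.dtype == np.float32 \
            else np.maximum(x, self.slope * x)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        out = grad.copy()
        out[self._neg] *= self.slope
        return out


class MaxPool1d(Layer):
    """Kernel-2 stride-2 max pooling, ceil mode (odd lengths padded with -inf)."""

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        bsz, ch, length = x.shape
        self._length = length
        if length % 2:
            pad = np.full((bsz, ch, 1), -np.inf, dtype=x.dtype)
            x = np.concatenate([x, pad], axis=2)
        a, b = x[:, :, 0::2], x[:, :, 1::2]
        self._right = b > a  # which element of each pair won
        return np.maximum(a, b)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        bsz, ch, half = grad.shape
        dx = np.zeros((bsz, ch, 2 * half), dtype=grad.dtype)
        right = self._right
        dx[:, :, 0::2] = np.where(right, 0, grad)
        dx[:, :, 1::2] = np.where(right, grad, 0)
        return dx[:, :, :self._length]


class GlobalMaxPool(Layer):
    """Max over the temporal axis; output (batch, channels)."""

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._arg, self._shape = x.argmax(axis=2), x.shape
        return x.max(axis=2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        dx = np.zeros(self._shape, dtype=grad.dtype)
        np.put_along_axis(dx, self._arg[..., None], grad[..., None], axis=2)
        return dx


class Dropout(Layer):
    """Inverted dropout on (batch, features); identity at inference."""

    def __init__(self, p: float, rng: np.random.Generator) -> None:
        self.p = p
        self.rng = rng
        self._mask = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not training or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask.astype(x.dtype)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return grad
        return grad * self._mask.astype(grad.dtype)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 init_range: tuple[float, float] = (-0.1, 0.1),
                 dtype=np.float32) -> None:
        self.w = rng.uniform(*init_range, size=(n_in, n_out)).astype(dtype)
        self.b = np.zeros(n_out, dtype=dtype)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.dw[...] = self._x.T @ grad
        self.db[...] = grad.sum(axis=0)
        dx = grad @ self.w.T
        self._x = None
        return dx

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]


class Network:
    """A plain sequential network with MSE regression loss."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return [p for layer in self.layers for p in layer.params()]

    def n_parameters(self) -> int:
        return sum(int(w.size) for w, _ in self.params())

    def state_arrays(self) -> dict[str, np.ndarray]:
        """All learnable parameters and batch-norm running stats, keyed stably."""
        out: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.layers):
            for j, (w, _) in enumerate(layer.params()):
                out[f"layer{i:02d}_p{j}"] = w
            if isinstance(layer, BatchNorm1d):
                out[f"layer{i:02d}_rmean"] = layer.run_mean
                out[f"layer{i:02d}_rvar"] = layer.run_var
        return out

    def load_state(self, arrays: dict[str, np.ndarray]) -> None:
        for key, target in self.state_arrays().items():
            target[...] = arrays[key]


class Adam:
    def __init__(self, params: list[tuple[np.ndarray, np.ndarray]],
                 lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(w) for w, _ in params]
        self.v = [np.zeros_like(w) for w, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for (w, g), m, v in zip(self.params, self.m, self.v):
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            w -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def train_mse(
    net: Network,
    x: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator,
    lr: float = 1e-3,
    batch_size: int = 256,
    epochs: int = 30,
) -> list[float]:
    """Minibatch Adam on the MSE objective; returns per-epoch mean loss."""
    opt = Adam(net.params(), lr=lr)
    n = x.shape[0]
    y = y.reshape(-1, 1).astype(x.dtype)
    history: list[float] = []
    for _ in range(epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            xb, yb = x[idx], y[idx]
            out = net.forward(xb, training=True)
            err = out - yb
            losses.append(float(np.mean(err ** 2)))
            net.backward(2.0 * err.astype(x.dtype) / err.shape[0])
            opt.step()
        history.append(float(np.mean(losses)))
    return history
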