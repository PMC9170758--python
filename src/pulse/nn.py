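"""Minimal numpy neural-network layers with backpropagation.

Implements exactly the pieces the Ψ-site classifier needs: valid 1-D
convolution over one-hot channels (as cross-correlation, via an im2col
matmul), batch normalization, PReLU, non-overlapping max pooling, dense
layers, inverted dropout, and an SGD-with-momentum update.  All
parameters are float32 and all randomness flows through a single
``numpy.random.Generator``, so training is bit-reproducible for a fixed
seed on a fixed platform.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    """Base class; layers with parameters override ``params``."""

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params(self) -> dict[str, np.ndarray]:
        return {}

    def grads(self) -> dict[str, np.ndarray]:
        return {}


class Conv1D(Layer):
    """Valid cross-correlation over the length axis of (n, L, C) inputs.

    Weights are stored as a (C*K, F) matrix whose rows are ordered
    channel-major then tap: row c*K + k corresponds to channel c at
    window offset k.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator):
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        scale = np.sqrt(2.0 / (in_channels * kernel))
        self.W = rng.normal(0.0, scale, (in_channels * kernel, out_channels)).astype(np.float32)
        self.b = np.zeros(out_channels, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def filter_weights(self, filter_id: int) -> np.ndarray:
        """Weights of one filter as a (kernel, channels) matrix."""
        return self.W.reshape(self.in_channels, self.kernel, self.out_channels)[
            :, :, filter_id
        ].T.copy()

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, L, C = x.shape
        if C != self.in_channels:
            raise ValueError(f"expected {self.in_channels} channels, got {C}")
        if L < self.kernel:
            raise ValueError(
                f"convolution kernel {self.kernel} exceeds input length {L}"
            )
        Lout = L - self.kernel + 1
        cols = sliding_window_view(x, self.kernel, axis=1)  # (n, Lout, C, K)
        cols2 = cols.reshape(n * Lout, C * self.kernel)
        out = cols2 @ self.W + self.b
        if training:
            self._cols2 = cols2
            self._x_shape = x.shape
        return out.reshape(n, Lout, self.out_channels)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, Lout, F = dout.shape
        d2 = dout.reshape(n * Lout, F)
        self.dW[...] = self._cols2.T @ d2
        self.db[...] = d2.sum(axis=0)
        dcols = (d2 @ self.W.T).reshape(n, Lout, self.in_channels, self.kernel)
        dx = np.zeros(self._x_shape, dtype=np.float32)
        for k in range(self.kernel):
            dx[:, k:k + Lout, :] += dcols[:, :, :, k]
        return dx

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}


class BatchNorm(Layer):
    """Per-channel batch normalization over all other axes.

    Running statistics (for inference) use an exponential moving average
    with the configured momentum.
    """

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-3):
        self.gamma = np.ones(channels, dtype=np.float32)
        self.beta = np.zeros(channels, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        flat = x.reshape(-1, x.shape[-1])
        if training:
            mean = flat.mean(axis=0)
            var = flat.var(axis=0)
            self.running_mean[...] = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var[...] = self.momentum * self.running_var + (1 - self.momentum) * var
            inv_std = 1.0 / np.sqrt(var + self.eps)
            xhat = (flat - mean) * inv_std
            self._xhat = xhat
            self._inv_std = inv_std
            self._shape = x.shape
            out = self.gamma * xhat + self.beta
        else:
            inv_std = 1.0 / np.sqrt(self.running_var + self.eps)
            out = self.gamma * (flat - self.running_mean) * inv_std + self.beta
        return out.reshape(x.shape).astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dflat = dout.reshape(-1, dout.shape[-1])
        m = dflat.shape[0]
        self.dgamma[...] = (dflat * self._xhat).sum(axis=0)
        self.dbeta[...] = dflat.sum(axis=0)
        dxhat = dflat * self.gamma
        dx = (self._inv_std / m) * (
            m * dxhat - dxhat.sum(axis=0) - self._xhat * (dxhat * self._xhat).sum(axis=0)
        )
        return dx.reshape(self._shape).astype(np.float32)

    def params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def grads(self):
        return {"gamma": self.dgamma, "beta": self.dbeta}

    def state(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}


class PReLU(Layer):
    """Parametric ReLU with one learnable negative-side slope per channel."""

    def __init__(self, channels: int, init_slope: float = 0.25):
        self.alpha = np.full(channels, init_slope, dtype=np.float32)
        self.dalpha = np.zeros_like(self.alpha)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            self._x = x
        return np.where(x > 0, x, self.alpha * x)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._x
        neg = x <= 0
        contrib = np.where(neg, dout * x, 0.0)
        self.dalpha[...] = contrib.reshape(-1, x.shape[-1]).sum(axis=0)
        return np.where(neg, dout * self.alpha, dout).astype(np.float32)

    def params(self):
        return {"alpha": self.alpha}

    def grads(self):
        return {"alpha": self.dalpha}


class MaxPool1D(Layer):
    """Non-overlapping max pooling over the length axis (width == stride)."""

    def __init__(self, width: int = 2):
        self.width = width

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, L, C = x.shape
        Lp = L // self.width
        xr = x[:, : Lp * self.width, :].reshape(n, Lp, self.width, C)
        if training:
            self._argmax = xr.argmax(axis=2)
            self._x_shape = x.shape
        return xr.max(axis=2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, Lp, C = dout.shape
        dxr = np.zeros((n, Lp, self.width, C), dtype=np.float32)
        np.put_along_axis(dxr, self._argmax[:, :, None, :], dout[:, :, None, :], axis=2)
        dx = np.zeros(self._x_shape, dtype=np.float32)
        dx[:, : Lp * self.width, :] = dxr.reshape(n, Lp * self.width, C)
        return dx


class Flatten(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / in_features)
        self.W = rng.normal(0.0, scale, (in_features, out_features)).astype(np.float32)
        self.b = np.zeros(out_features, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dW[...] = self._x.T @ dout
        self.db[...] = dout.sum(axis=0)
        return (dout @ self.W.T).astype(np.float32)

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, p: float, rng: np.random.Generator):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not training or self.p == 0.0:
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self.p == 0.0:
            return dout
        return dout * self._mask


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_loss(p: np.ndarray, y: np.ndarray, eps: float = 1e-7) -> float:
    p = np.clip(p, eps, 1.0 - eps)
    return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())


class SGDMomentum:
    """SGD with classical momentum and optional global-norm gradient clipping
    (clip_norm <= 0 disables clipping)."""

    def __init__(self, layers, lr: float, momentum: float, clip_norm: float = 5.0):
        self.layers = [l for l in layers if l.params()]
        self.lr = lr
        self.momentum = momentum
        self.clip_norm = clip_norm
        self.velocity = [
            {k: np.zeros_like(v) for k, v in layer.params().items()}
            for layer in self.layers
        ]

    def step(self) -> None:
        scale = 1.0
        if self.clip_norm > 0:
            sq = 0.0
            for layer in self.layers:
                for g in layer.grads().values():
                    sq += float(np.sum(np.square(g, dtype=np.float64)))
            norm = np.sqrt(sq)
            if norm > self.clip_norm:
                scale = self.clip_norm / norm
        for layer, vel in zip(self.layers, self.velocity):
            grads = layer.grads()
            for name, param in layer.params().items():
                v = vel[name]
                v *= self.momentum
                v -= self.lr * scale * grads[name]
                param += v
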