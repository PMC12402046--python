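"""Minimal 3D convolutional network engine in numpy.

Implements exactly the layers the repeating-block classifier needs —
3D convolution (stride 1, 'same' padding, via im2col and matrix
multiplication), batch normalization, ReLU, 2x2x2 max pooling, global
average pooling, dropout, a dense head — together with reverse-mode
gradients and an Adam optimizer.  Everything is float32 and seeded;
training on one CPU thread is bit-reproducible.

Data layout is channels-first: ``(N, C, D, H, W)``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv3D", "BatchNorm3D", "ReLU", "MaxPool3D", "GlobalAvgPool",
           "Dropout", "Dense", "Sequential3D", "Adam", "bce_with_logits", "sigmoid"]

_DT = np.float32


def sigmoid(z):
    z = np.asarray(z, dtype=np.float64)
    return 1.0 / (1.0 + np.exp(-z))


def bce_with_logits(logits, targets):
    """Mean binary cross-entropy and its gradient w.r.t. the logits."""
    z = np.asarray(logits, dtype=np.float64)
    y = np.asarray(targets, dtype=np.float64)
    # softplus formulation, numerically stable for large |z|
    loss = np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z))))
    grad = (sigmoid(z) - y) / z.size
    return float(loss), grad.astype(_DT)


class Layer:
    def parameters(self):
        """Yield (param_array, grad_array) pairs in a stable order."""
        return []

    def forward(self, x, train=False, rng=None):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - interface
        raise NotImplementedError


class Conv3D(Layer):
    """3D convolution, kernel k, stride 1, zero padding k//2 ('same').

    Implemented as one GEMM over an offset-stacked column matrix: for each
    of the k^3 kernel offsets a contiguous shifted view of the padded
    input is copied once, giving a (C*k^3, N*D*H*W) matrix that both the
    forward product and the weight gradient reuse.
    """

    def __init__(self, in_channels, out_channels, kernel=3, rng=None):
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kernel ** 3
        self.k = kernel
        self.in_channels = in_channels
        self.out_channels = out_channels
        # weight rows ordered (offset, channel) to match _columns
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, out_channels)).astype(_DT)
        self.b = np.zeros(out_channels, dtype=_DT)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._cols = None
        self._xshape = None

    def parameters(self):
        return [(self.w, self.dw), (self.b, self.db)]

    def _columns(self, x):
        n, c, d, h, w = x.shape
        k, p = self.k, self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        cols = np.empty((k * k * k, c, n, d, h, w), dtype=_DT)
        for i in range(k):
            for j in range(k):
                for l in range(k):
                    cols[(i * k + j) * k + l] = xp[:, :, i:i + d, j:j + h, l:l + w].transpose(1, 0, 2, 3, 4)
        return cols.reshape(k ** 3 * c, n * d * h * w)

    def forward(self, x, train=False, rng=None):
        n, c, d, h, w = x.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {c}")
        cols = self._columns(x)
        out = (self.w.T @ cols).reshape(self.out_channels, n, d, h, w)
        out += self.b[:, None, None, None, None]
        self._cols = cols if train else None
        self._xshape = x.shape
        return np.ascontiguousarray(out.transpose(1, 0, 2, 3, 4))

    def backward(self, grad):
        n, f, d, h, w = grad.shape
        c, k = self.in_channels, self.k
        p = k // 2
        gmat = np.ascontiguousarray(grad.transpose(1, 0, 2, 3, 4)).reshape(f, -1)
        self.dw[...] = (gmat @ self._cols.T).T
        self.db[...] = gmat.sum(axis=1)
        # input gradient: scatter w^T-projected grads back over the offsets
        dcols = (self.w @ gmat).reshape(k * k * k, c, n, d, h, w)
        dxp = np.zeros((c, n, d + 2 * p, h + 2 * p, w + 2 * p), dtype=_DT)
        for i in range(k):
            for j in range(k):
                for l in range(k):
                    dxp[:, :, i:i + d, j:j + h, l:l + w] += dcols[(i * k + j) * k + l]
        self._cols = None
        return np.ascontiguousarray(
            dxp[:, :, p:p + d, p:p + h, p:p + w].transpose(1, 0, 2, 3, 4))


class BatchNorm3D(Layer):
    """Per-channel batch normalization over (N, D, H, W)."""

    def __init__(self, channels, momentum=0.1, eps=1e-5):
        self.gamma = np.ones(channels, dtype=_DT)
        self.beta = np.zeros(channels, dtype=_DT)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels, dtype=_DT)
        self.running_var = np.ones(channels, dtype=_DT)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def parameters(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]

    @staticmethod
    def _bc(v):
        return v[None, :, None, None, None]

    def forward(self, x, train=False, rng=None):
        axes = (0, 2, 3, 4)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - self._bc(mean)) * self._bc(inv)
        if train:
            self._cache = (xhat, inv)
        return (self._bc(self.gamma) * xhat + self._bc(self.beta)).astype(_DT)

    def backward(self, grad):
        xhat, inv = self._cache
        axes = (0, 2, 3, 4)
        m = grad.shape[0] * grad.shape[2] * grad.shape[3] * grad.shape[4]
        self.dgamma[...] = np.sum(grad * xhat, axis=axes)
        self.dbeta[...] = np.sum(grad, axis=axes)
        dx = (self._bc(self.gamma * inv) / m) * (
            m * grad - self._bc(self.dbeta) - xhat * self._bc(self.dgamma))
        self._cache = None
        return dx.astype(_DT)


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class MaxPool3D(Layer):
    """2x2x2 max pooling, stride 2; ties go to the first occurrence."""

    def forward(self, x, train=False, rng=None):
        n, c, d, h, w = x.shape
        if d % 2 or h % 2 or w % 2:
            raise ValueError(f"spatial dims must be even for 2x pooling, got {x.shape}")
        r = x.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2)
        out = r.max(axis=(3, 5, 7))
        if train:
            # winner mask; ties (e.g. in constant padding regions) split
            # the gradient across the tied cells, a valid subgradient
            mx = out[:, :, :, None, :, None, :, None]
            self._mask = (r == mx)
            self._counts = self._mask.sum(axis=(3, 5, 7))
        self._inshape = x.shape
        return out

    def backward(self, grad):
        n, c, d, h, w = self._inshape
        g = (grad / self._counts)[:, :, :, None, :, None, :, None]
        out = self._mask * g
        return out.reshape(n, c, d, h, w)


class GlobalAvgPool(Layer):
    def forward(self, x, train=False, rng=None):
        self._inshape = x.shape
        return x.mean(axis=(2, 3, 4))

    def backward(self, grad):
        n, c, d, h, w = self._inshape
        return np.broadcast_to(grad[:, :, None, None, None] / (d * h * w),
                               self._inshape).astype(grad.dtype)


class Dropout(Layer):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, rate=0.3):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self._mask = None

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("dropout in training mode needs an rng")
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return (x * self._mask).astype(_DT)

    def backward(self, grad):
        if self._mask is None:
            return grad
        return (grad * self._mask).astype(grad.dtype)


class Dense(Layer):
    def __init__(self, in_features, out_features=1, rng=None):
        rng = rng or np.random.default_rng()
        self.w = rng.normal(0.0, np.sqrt(2.0 / in_features),
                            size=(in_features, out_features)).astype(_DT)
        self.b = np.zeros(out_features, dtype=_DT)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def parameters(self):
        return [(self.w, self.dw), (self.b, self.db)]

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad):
        self.dw[...] = self._x.T @ grad
        self.db[...] = grad.sum(axis=0)
        return grad @ self.w.T


class Sequential3D:
    """An ordered layer stack with a single forward/backward pass."""

    def __init__(self, layers):
        self.layers = list(layers)

    def forward(self, x, train=False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def parameters(self):
        out = []
        for layer in self.layers:
            out.extend(layer.parameters())
        return out

    def get_state(self):
        """Deep copy of all parameters and batch-norm running stats."""
        state = [np.copy(p) for p, _ in self.parameters()]
        for layer in self.layers:
            if isinstance(layer, BatchNorm3D):
                state.append(layer.running_mean.copy())
                state.append(layer.running_var.copy())
        return state

    def set_state(self, state):
        it = iter(state)
        for p, _ in self.parameters():
            p[...] = next(it)
        for layer in self.layers:
            if isinstance(layer, BatchNorm3D):
                layer.running_mean[...] = next(it)
                layer.running_var[...] = next(it)


class Adam:
    """Adam with the standard bias correction (beta1=0.9, beta2=0.999)."""

    def __init__(self, params, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self, lr):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m += (1.0 - b1) * (g - m)
            v += (1.0 - b2) * (g * g - v)
            p -= (lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)).astype(p.dtype)
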