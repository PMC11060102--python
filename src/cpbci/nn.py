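"""Minimal numpy layer library with manual backpropagation.

Provides exactly the pieces the two deep decoders need: temporal and
depthwise convolutions, batch normalization, ELU/ReLU, average pooling,
dropout, dense layers with optional max-norm constraints, an Adam optimizer
and a cosine direction loss. Forward passes in evaluation mode are
deterministic; training is reproducible given a seed.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Sequential",
    "Dense",
    "BatchNorm",
    "ELU",
    "ReLU",
    "Dropout",
    "AvgPoolTime",
    "Flatten",
    "TemporalConv",
    "DepthwiseSpatialConv",
    "DepthwiseTemporalConv",
    "PointwiseConv",
    "Adam",
    "cosine_loss",
]


class Param:
    __slots__ = ("value", "grad", "max_norm", "norm_axes")

    def __init__(self, value: np.ndarray, max_norm: float | None = None, norm_axes=None):
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)
        self.max_norm = max_norm
        self.norm_axes = norm_axes

    def renorm(self) -> None:
        """Project back onto the max-norm ball (per filter) after an update."""
        if self.max_norm is None:
            return
        norms = np.sqrt(np.sum(self.value**2, axis=self.norm_axes, keepdims=True))
        factor = np.minimum(1.0, self.max_norm / np.maximum(norms, 1e-12))
        self.value *= factor


class Layer:
    train: bool = True

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def set_train(self, flag: bool) -> None:
        for lyr in self.layers:
            lyr.train = flag
            if isinstance(lyr, Sequential):
                lyr.set_train(flag)

    def params(self) -> list[Param]:
        return [p for lyr in self.layers for p in lyr.params()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for lyr in self.layers:
            x = lyr.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for lyr in reversed(self.layers):
            dy = lyr.backward(dy)
        return dy


class Dense(Layer):
    """Affine map applied to the last axis; leading axes are batch."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 max_norm: float | None = None, bias: bool = True):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = Param(rng.uniform(-limit, limit, (n_in, n_out)),
                       max_norm=max_norm, norm_axes=(0,))
        self.b = Param(np.zeros(n_out)) if bias else None

    def params(self):
        return [self.W] + ([self.b] if self.b is not None else [])

    def forward(self, x):
        self._x = x
        y = x @ self.W.value
        if self.b is not None:
            y = y + self.b.value
        return y

    def backward(self, dy):
        x2 = self._x.reshape(-1, self._x.shape[-1])
        dy2 = dy.reshape(-1, dy.shape[-1])
        self.W.grad += x2.T @ dy2
        if self.b is not None:
            self.b.grad += dy2.sum(axis=0)
        return dy @ self.W.value.T


class BatchNorm(Layer):
    """Batch normalization over all axes except ``feature_axis``."""

    def __init__(self, n_features: int, feature_axis: int = 1,
                 momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(n_features))
        self.beta = Param(np.zeros(n_features))
        self.axis = feature_axis
        self.momentum = momentum
        self.eps = eps
        self.run_mean = np.zeros(n_features)
        self.run_var = np.ones(n_features)

    def params(self):
        return [self.gamma, self.beta]

    def _shape(self, x):
        shape = [1] * x.ndim
        shape[self.axis] = x.shape[self.axis]
        return shape

    def forward(self, x):
        shape = self._shape(x)
        axes = tuple(i for i in range(x.ndim) if i != self.axis % x.ndim)
        if self.train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
            self._axes = axes
            self._m = x.size // x.shape[self.axis % x.ndim]
            self._inv_sd = (1.0 / np.sqrt(var + self.eps)).reshape(shape)
            self._xhat = (x - mean.reshape(shape)) * self._inv_sd
            return self.gamma.value.reshape(shape) * self._xhat + self.beta.value.reshape(shape)
        inv_sd = 1.0 / np.sqrt(self.run_var + self.eps)
        xhat = (x - self.run_mean.reshape(shape)) * inv_sd.reshape(shape)
        return self.gamma.value.reshape(shape) * xhat + self.beta.value.reshape(shape)

    def backward(self, dy):
        shape = self._shape(dy)
        axes = self._axes
        self.gamma.grad += (dy * self._xhat).sum(axis=axes)
        self.beta.grad += dy.sum(axis=axes)
        g = self.gamma.value.reshape(shape)
        dxhat = dy * g
        m = self._m
        term = (
            dxhat
            - dxhat.mean(axis=axes, keepdims=True)
            - self._xhat * (dxhat * self._xhat).sum(axis=axes, keepdims=True) / m
        )
        return term * self._inv_sd


class ELU(Layer):
    def __init__(self, alpha: float = 1.0):
        self.alpha = alpha

    def forward(self, x):
        self._x = x
        return np.where(x > 0, x, self.alpha * (np.exp(np.minimum(x, 0)) - 1.0))

    def backward(self, dy):
        x = self._x
        return dy * np.where(x > 0, 1.0, self.alpha * np.exp(np.minimum(x, 0)))


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Dropout(Layer):
    def __init__(self, p: float, rng: np.random.Generator):
        self.p = p
        self.rng = rng

    def forward(self, x):
        if not self.train or self.p <= 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class AvgPoolTime(Layer):
    """Average pooling over the trailing (time) axis by an integer factor."""

    def __init__(self, factor: int):
        self.factor = factor

    def forward(self, x):
        t = x.shape[-1] - x.shape[-1] % self.factor
        self._t_in = x.shape[-1]
        xt = x[..., :t]
        self._shape = xt.shape
        y = xt.reshape(*xt.shape[:-1], t // self.factor, self.factor).mean(axis=-1)
        return y

    def backward(self, dy):
        dx = np.repeat(dy / self.factor, self.factor, axis=-1)
        if dx.shape[-1] < self._t_in:
            pad = [(0, 0)] * (dx.ndim - 1) + [(0, self._t_in - dx.shape[-1])]
            dx = np.pad(dx, pad)
        return dx


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class TemporalConv(Layer):
    """(N, 1, C, T) -> (N, F, C, T): F temporal filters shared across channels."""

    def __init__(self, n_filters: int, k: int, rng: np.random.Generator):
        if k % 2 == 0:
            raise ValueError("kernel length must be odd for symmetric padding")
        self.k = k
        limit = np.sqrt(6.0 / (k + k))
        self.W = Param(rng.uniform(-limit, limit, (n_filters, k)))

    def params(self):
        return [self.W]

    def forward(self, x):
        n, f_in, c, t = x.shape
        if f_in != 1:
            raise ValueError("TemporalConv expects a single input map")
        p = (self.k - 1) // 2
        self._xpad = np.pad(x, ((0, 0), (0, 0), (0, 0), (p, p)))
        self._t = t
        W = self.W.value
        y = np.zeros((n, W.shape[0], c, t))
        for j in range(self.k):
            y += W[:, j][None, :, None, None] * self._xpad[:, :, :, j : j + t]
        return y

    def backward(self, dy):
        t = self._t
        p = (self.k - 1) // 2
        dxpad = np.zeros_like(self._xpad)
        for j in range(self.k):
            self.W.grad[:, j] += np.einsum("nfct,noct->f", dy, self._xpad[:, :, :, j : j + t])
            dxpad[:, 0, :, j : j + t] += np.einsum(
                "nfct,f->nct", dy, self.W.value[:, j]
            )
        return dxpad[:, :, :, p : p + t]


class DepthwiseSpatialConv(Layer):
    """(N, F, C, T) -> (N, F*D, 1, T): D spatial filters per temporal map."""

    def __init__(self, n_maps: int, depth: int, n_channels: int, rng: np.random.Generator,
                 max_norm: float | None = 1.0):
        limit = np.sqrt(6.0 / (n_channels + 1))
        self.W = Param(
            rng.uniform(-limit, limit, (n_maps, depth, n_channels)),
            max_norm=max_norm, norm_axes=(2,),
        )

    def params(self):
        return [self.W]

    def forward(self, x):
        self._x = x
        y = np.einsum("nfct,fdc->nfdt", x, self.W.value)
        n, f, d, t = y.shape
        self._fd = (f, d)
        return y.reshape(n, f * d, 1, t)

    def backward(self, dy):
        f, d = self._fd
        n, fd, _, t = dy.shape
        dy4 = dy.reshape(n, f, d, t)
        self.W.grad += np.einsum("nfdt,nfct->fdc", dy4, self._x)
        return np.einsum("nfdt,fdc->nfct", dy4, self.W.value)


class DepthwiseTemporalConv(Layer):
    """(N, G, 1, T) -> (N, G, 1, T): one temporal filter per map."""

    def __init__(self, n_maps: int, k: int, rng: np.random.Generator):
        if k % 2 == 0:
            raise ValueError("kernel length must be odd for symmetric padding")
        self.k = k
        limit = np.sqrt(6.0 / (k + k))
        self.W = Param(rng.uniform(-limit, limit, (n_maps, k)))

    def params(self):
        return [self.W]

    def forward(self, x):
        n, g, c, t = x.shape
        p = (self.k - 1) // 2
        self._xpad = np.pad(x, ((0, 0), (0, 0), (0, 0), (p, p)))
        self._t = t
        y = np.zeros_like(x)
        for j in range(self.k):
            y += self.W.value[:, j][None, :, None, None] * self._xpad[:, :, :, j : j + t]
        return y

    def backward(self, dy):
        t = self._t
        p = (self.k - 1) // 2
        dxpad = np.zeros_like(self._xpad)
        for j in range(self.k):
            self.W.grad[:, j] += np.einsum("ngct,ngct->g", dy, self._xpad[:, :, :, j : j + t])
            dxpad[:, :, :, j : j + t] += dy * self.W.value[:, j][None, :, None, None]
        return dxpad[:, :, :, p : p + t]


class PointwiseConv(Layer):
    """(N, G_in, C, T) -> (N, G_out, C, T): 1x1 mixing across maps."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = Param(rng.uniform(-limit, limit, (n_out, n_in)))

    def params(self):
        return [self.W]

    def forward(self, x):
        self._x = x
        return np.einsum("ngct,hg->nhct", x, self.W.value)

    def backward(self, dy):
        self.W.grad += np.einsum("nhct,ngct->hg", dy, self._x)
        return np.einsum("nhct,hg->ngct", dy, self.W.value)


class Adam:
    """Adaptive-moment gradient descent with post-step max-norm projection."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * p.grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * p.grad**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
            p.renorm()


def cosine_loss(pred: np.ndarray, labels: np.ndarray, eps: float = 1e-8):
    """Mean 1 - cos(pred, label) and its gradient w.r.t. pred.

    Labels are unit vectors; predictions are free 2-vectors. Minimizing this
    surrogate minimizes the angle between prediction and label.
    """
    n = pred.shape[0]
    norms = np.sqrt((pred**2).sum(axis=1, keepdims=True)) + eps
    phat = pred / norms
    cos = (phat * labels).sum(axis=1, keepdims=True)
    loss = float((1.0 - cos).mean())
    # d cos / d pred = (label - cos * phat) / |pred|
    dpred = -(labels - cos * phat) / norms / n
    return loss, dpred
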