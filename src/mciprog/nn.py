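"""Minimal 3D neural-network layers with explicit backpropagation.

Compact building blocks for small volumetric networks on CPU: grouped 3D
convolutions (depthwise + pointwise pairs give separable convolutions),
ReLU, global average pooling, dense layers, and an Adam optimizer with a
milestone learning-rate schedule.  Everything is float64 NumPy; forward
passes cache what the matching ``backward`` needs, and parameter gradients
accumulate into ``Param.grad``.

Convolutions are evaluated with a loop over the k^3 kernel offsets, each a
strided slice plus an einsum over channels — at the few-channel, 32^3 scale
this is faster and simpler than an im2col scatter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .errors import ShapeError


@dataclass
class Param:
    value: np.ndarray
    grad: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []


class Conv3d(Layer):
    """Grouped valid 3D convolution, isotropic kernel and stride."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int = 1, groups: int = 1,
                 rng: np.random.Generator | None = None) -> None:
        if in_channels % groups or out_channels % groups:
            raise ShapeError("channels must be divisible by groups")
        rng = rng or np.random.default_rng(0)
        cg = in_channels // groups
        fan_in = cg * kernel ** 3
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                  (out_channels, cg, kernel, kernel, kernel)))
        self.b = Param(np.zeros(out_channels))
        self.stride = stride
        self.groups = groups
        self.kernel = kernel
        self.in_channels = in_channels
        self.out_channels = out_channels
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def _out_spatial(self, shape: tuple[int, ...]) -> tuple[int, int, int]:
        k, s = self.kernel, self.stride
        out = tuple((d - k) // s + 1 for d in shape)
        if any(d < 1 for d in out):
            raise ShapeError(
                f"input spatial shape {shape} too small for kernel {k}")
        return out  # type: ignore[return-value]

    def forward(self, x: np.ndarray) -> np.ndarray:
        N, C = x.shape[:2]
        if C != self.in_channels:
            raise ShapeError(f"expected {self.in_channels} channels, got {C}")
        k, s, g = self.kernel, self.stride, self.groups
        Do, Ho, Wo = self._out_spatial(x.shape[2:])
        og, cg = self.out_channels // g, self.in_channels // g
        out = np.zeros((N, self.out_channels, Do, Ho, Wo))
        for gi in range(g):
            xg = x[:, gi * cg:(gi + 1) * cg]
            Wg = self.W.value[gi * og:(gi + 1) * og]
            acc = out[:, gi * og:(gi + 1) * og]
            for i, j, l in product(range(k), repeat=3):
                xs = xg[:, :, i:i + s * Do:s, j:j + s * Ho:s, l:l + s * Wo:s]
                acc += np.einsum("oc,ncdhw->nodhw", Wg[:, :, i, j, l], xs)
        out += self.b.value[None, :, None, None, None]
        self._x = x
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._x
        assert x is not None, "forward must run before backward"
        k, s, g = self.kernel, self.stride, self.groups
        Do, Ho, Wo = dout.shape[2:]
        og, cg = self.out_channels // g, self.in_channels // g
        dx = np.zeros_like(x)
        for gi in range(g):
            xg = x[:, gi * cg:(gi + 1) * cg]
            Wg = self.W.value[gi * og:(gi + 1) * og]
            dog = dout[:, gi * og:(gi + 1) * og]
            dWg = self.W.grad[gi * og:(gi + 1) * og]
            dxg = dx[:, gi * cg:(gi + 1) * cg]
            for i, j, l in product(range(k), repeat=3):
                xs = xg[:, :, i:i + s * Do:s, j:j + s * Ho:s, l:l + s * Wo:s]
                dWg[:, :, i, j, l] += np.einsum("nodhw,ncdhw->oc", dog, xs)
                dxg[:, :, i:i + s * Do:s, j:j + s * Ho:s, l:l + s * Wo:s] += \
                    np.einsum("oc,nodhw->ncdhw", Wg[:, :, i, j, l], dog)
        self.b.grad += dout.sum(axis=(0, 2, 3, 4))
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class GlobalAvgPool3d(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._spatial = x.shape[2:]
        return x.mean(axis=(2, 3, 4))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        D, H, W = self._spatial
        scale = 1.0 / (D * H * W)
        return np.broadcast_to(
            dout[:, :, None, None, None] * scale,
            dout.shape + self._spatial).copy()


class AvgPool3d(Layer):
    """Valid average pooling with cubic window and equal stride."""

    def __init__(self, kernel: int = 2) -> None:
        self.k = kernel

    def forward(self, x: np.ndarray) -> np.ndarray:
        k = self.k
        self._in_shape = x.shape
        D, H, W = (d // k for d in x.shape[2:])
        if min(D, H, W) < 1:
            raise ShapeError(
                f"spatial shape {x.shape[2:]} too small for pool {k}")
        v = x[:, :, :D * k, :H * k, :W * k].reshape(
            x.shape[0], x.shape[1], D, k, H, k, W, k)
        return v.mean(axis=(3, 5, 7))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        k = self.k
        N, C, D, H, W = dout.shape
        dx = np.zeros(self._in_shape)
        expanded = np.repeat(np.repeat(np.repeat(
            dout, k, axis=2), k, axis=3), k, axis=4) / k ** 3
        dx[:, :, :D * k, :H * k, :W * k] = expanded
        return dx


class BatchNorm3d(Layer):
    """Per-channel batch normalization over (batch, spatial) axes.

    Standardizing activations keeps small absolute deviations (e.g. a focal
    contraction on a near-constant volume-change map) from vanishing next to
    large constant offsets.  Inference uses exponential running statistics.
    """

    def __init__(self, channels: int, momentum: float = 0.1,
                 eps: float = 1e-5) -> None:
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps
        self.training = False

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        axes = (0, 2, 3, 4)
        if self.training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean[None, :, None, None, None]) / \
            self._std[None, :, None, None, None]
        self._train_pass = self.training
        return (self.gamma.value[None, :, None, None, None] * self._xhat
                + self.beta.value[None, :, None, None, None])

    def backward(self, dout: np.ndarray) -> np.ndarray:
        axes = (0, 2, 3, 4)
        xhat = self._xhat
        self.gamma.grad += (dout * xhat).sum(axis=axes)
        self.beta.grad += dout.sum(axis=axes)
        g = self.gamma.value[None, :, None, None, None]
        dxhat = dout * g
        inv_std = 1.0 / self._std[None, :, None, None, None]
        if not self._train_pass:
            return dxhat * inv_std
        m = dout[:, 0].size  # N * D * H * W per channel
        return (inv_std / m) * (
            m * dxhat
            - dxhat.sum(axis=axes, keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=axes, keepdims=True))


class Dropout(Layer):
    """Inverted dropout; active only when ``training`` is set."""

    def __init__(self, p: float) -> None:
        if not 0.0 <= p < 1.0:
            raise ShapeError("dropout probability must lie in [0, 1)")
        self.p = p
        self.training = False
        self.rng = np.random.default_rng(0)
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if not self.training or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout if self._mask is None else dout * self._mask


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int,
                 rng: np.random.Generator | None = None) -> None:
        rng = rng or np.random.default_rng(0)
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / in_dim),
                                  (in_dim, out_dim)))
        self.b = Param(np.zeros(out_dim))
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        assert self._x is not None
        self.W.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.W.value.T


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Adam:
    """Adam with a milestone LR schedule (lr *= gamma at each milestone)."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8,
                 milestones: tuple[int, ...] = (),
                 gamma: float = 0.3,
                 weight_decay: float = 0.0,
                 l1_decay: float = 0.0) -> None:
        self.params = params
        self.base_lr = lr
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.milestones = tuple(milestones)
        self.gamma = gamma
        self.weight_decay = weight_decay
        self.l1_decay = l1_decay
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def set_epoch(self, epoch: int) -> None:
        """Apply the schedule for a 0-based epoch index."""
        decays = sum(1 for ms in self.milestones if epoch >= ms)
        self.lr = self.base_lr * self.gamma ** decays

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            if not p.grad.any() and not m.any():
                continue    # untouched heads (zero task weight) stay put
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad ** 2
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if self.weight_decay and p.value.ndim >= 2:   # skip biases
                p.value -= self.lr * self.weight_decay * p.value
            if self.l1_decay and p.value.ndim >= 2:
                # proximal soft-threshold: exact zeros for irrelevant weights
                shrink = self.lr * self.l1_decay
                p.value = np.sign(p.value) * np.maximum(
                    np.abs(p.value) - shrink, 0.0)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0
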