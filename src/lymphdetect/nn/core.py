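"""A compact CPU neural-network engine on numpy.

Implements exactly the layers the detection pipeline needs — N-dimensional
convolution ('same' padding, integer stride), batch normalisation, 2x max
pooling, nearest-neighbour upsampling, dense layers, Dice and
softmax-cross-entropy losses, and Adam — with hand-written backward passes.
Every backward pass is covered by numerical gradient checks in the test
suite.

Convolutions use an offset-accumulation scheme: for each kernel offset the
strided input view is contracted against the corresponding weight slice
(``tensordot``), so memory stays linear in the input size (no im2col
blow-up), which matters for 64^3 two-channel patches.

Arrays are channels-first: (N, C, H, W) in 2D, (N, C, D, H, W) in 3D.
All randomness flows through an explicit ``numpy.random.Generator``.
"""

from __future__ import annotations

import hashlib
from itertools import product
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "ConvND",
    "BatchNorm",
    "ReLU",
    "MaxPool",
    "Upsample",
    "GlobalAvgPool",
    "Dense",
    "Adam",
    "sigmoid",
    "dice_loss_and_grad",
    "softmax_cross_entropy_and_grad",
    "state_hash",
]


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.name = name

    def zero_grad(self) -> None:
        self.grad.fill(0.0)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class ConvND(Layer):
    """N-dimensional convolution with 'same' padding and integer stride.

    Output spatial size is ceil(n / stride) per axis.  He-normal init.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int = 3,
        stride: int = 1,
        nd: int = 2,
        rng: np.random.Generator | None = None,
        bias: bool = True,
        name: str = "conv",
    ):
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * kernel**nd
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_channels, in_channels) + (kernel,) * nd)
        self.weight = Param(w, f"{name}.weight")
        self.bias = Param(np.zeros(out_channels), f"{name}.bias") if bias else None
        self.kernel = kernel
        self.stride = stride
        self.nd = nd

    def params(self) -> list[Param]:
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def _geometry(self, spatial: tuple[int, ...]):
        s, k = self.stride, self.kernel
        out = tuple(-(-n // s) for n in spatial)  # ceil
        pads = []
        for n, o in zip(spatial, out):
            total = max((o - 1) * s + k - n, 0)
            pads.append((total // 2, total - total // 2))
        return out, pads

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        spatial = x.shape[2:]
        out_sp, pads = self._geometry(spatial)
        xp = np.pad(x, [(0, 0), (0, 0)] + pads)
        self._x_shape, self._out_sp, self._pads = x.shape, out_sp, pads
        W = self.weight.value
        self._xp = xp
        acc = np.zeros((W.shape[0], x.shape[0]) + out_sp, dtype=x.dtype)
        s = self.stride
        wc = W.astype(x.dtype, copy=False)
        for off in product(range(self.kernel), repeat=self.nd):
            sl = tuple(
                slice(o, o + n_out * s, s) for o, n_out in zip(off, out_sp)
            )
            xs = xp[(slice(None), slice(None)) + sl]  # (N, C, *S)
            acc += np.tensordot(wc[(slice(None), slice(None)) + off], xs, axes=([1], [1]))
        out = np.moveaxis(acc, 0, 1)
        if self.bias is not None:
            out = out + self.bias.value.reshape((1, -1) + (1,) * self.nd).astype(
                x.dtype, copy=False
            )
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        out_sp, pads = self._out_sp, self._pads
        W = self.weight.value
        s = self.stride
        sp_axes = tuple(range(2, 2 + self.nd))
        if self.bias is not None:
            self.bias.grad += dout.sum(axis=(0,) + sp_axes)
        n, c = self._x_shape[:2]
        xp = self._xp
        dxp = np.zeros_like(xp)
        wc = W.astype(dout.dtype, copy=False)
        # flatten batch+spatial once so each offset contraction is a clean GEMM
        dmat = np.ascontiguousarray(np.moveaxis(dout, 1, -1)).reshape(-1, W.shape[0])
        for off in product(range(self.kernel), repeat=self.nd):
            sl = tuple(slice(o, o + n_out * s, s) for o, n_out in zip(off, out_sp))
            idx = (slice(None), slice(None)) + sl
            xs = xp[idx]
            xmat = np.ascontiguousarray(np.moveaxis(xs, 1, -1)).reshape(-1, c)
            self.weight.grad[(slice(None), slice(None)) + off] += (dmat.T @ xmat)
            dxs = np.tensordot(wc[(slice(None), slice(None)) + off], dout, axes=([0], [1]))
            dxp[idx] += np.moveaxis(dxs, 0, 1)
        crop = tuple(
            slice(p[0], p[0] + sz) for p, sz in zip(pads, self._x_shape[2:])
        )
        return dxp[(slice(None), slice(None)) + crop]


class BatchNorm(Layer):
    """Batch normalisation over (batch, spatial) per channel with running stats."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5, name: str = "bn"):
        self.gamma = Param(np.ones(channels), f"{name}.gamma")
        self.beta = Param(np.zeros(channels), f"{name}.beta")
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def _shape(self, x):
        return (1, -1) + (1,) * (x.ndim - 2)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        axes = (0,) + tuple(range(2, x.ndim))
        shp = self._shape(x)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
            self._m = x.size // x.shape[1]
            self._xc = x - mean.reshape(shp)
            self._ivstd = 1.0 / np.sqrt(var + self.eps)
            self._xhat = self._xc * self._ivstd.reshape(shp)
            g = self.gamma.value.reshape(shp).astype(x.dtype, copy=False)
            b = self.beta.value.reshape(shp).astype(x.dtype, copy=False)
            return g * self._xhat + b
        ivstd = (1.0 / np.sqrt(self.running_var + self.eps)).astype(x.dtype, copy=False)
        xhat = (x - self.running_mean.reshape(shp).astype(x.dtype, copy=False)) * ivstd.reshape(shp)
        g = self.gamma.value.reshape(shp).astype(x.dtype, copy=False)
        b = self.beta.value.reshape(shp).astype(x.dtype, copy=False)
        return g * xhat + b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        axes = (0,) + tuple(range(2, dout.ndim))
        shp = self._shape(dout)
        m = self._m
        self.gamma.grad += (dout * self._xhat).sum(axis=axes)
        self.beta.grad += dout.sum(axis=axes)
        dxhat = dout * self.gamma.value.reshape(shp).astype(dout.dtype, copy=False)
        ivstd = self._ivstd.reshape(shp).astype(dout.dtype, copy=False)
        dvar = (dxhat * self._xc).sum(axis=axes).reshape(shp) * (-0.5) * ivstd**3
        dmean = (-dxhat * ivstd).sum(axis=axes).reshape(shp) + dvar * (
            -2.0 * self._xc.mean(axis=axes).reshape(shp)
        )
        return dxhat * ivstd + dvar * 2.0 * self._xc / m + dmean / m


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, 0.0)


class MaxPool(Layer):
    """Factor-2 max pooling; spatial dims must be even."""

    def __init__(self, nd: int = 2):
        self.nd = nd

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c = x.shape[:2]
        spatial = x.shape[2:]
        if any(s % 2 for s in spatial):
            raise ValueError(f"MaxPool needs even spatial dims, got {spatial}")
        out_sp = tuple(s // 2 for s in spatial)
        shape = (n, c) + sum(((s, 2) for s in out_sp), ())
        xr = x.reshape(shape)
        # bring the window axes last: (N, C, *out, 2**nd)
        order = [0, 1] + [2 + 2 * i for i in range(self.nd)] + [3 + 2 * i for i in range(self.nd)]
        xr = xr.transpose(order).reshape((n, c) + out_sp + (2**self.nd,))
        self._arg = np.argmax(xr, axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(xr, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c = self._in_shape[:2]
        out_sp = dout.shape[2:]
        dxr = np.zeros((n, c) + out_sp + (2**self.nd,), dtype=dout.dtype)
        np.put_along_axis(dxr, self._arg[..., None], dout[..., None], axis=-1)
        shape = (n, c) + out_sp + (2,) * self.nd
        dxr = dxr.reshape(shape)
        order = [0, 1] + sum(([2 + i, 2 + self.nd + i] for i in range(self.nd)), [])
        return dxr.transpose(order).reshape(self._in_shape)


class Upsample(Layer):
    """Nearest-neighbour factor-2 upsampling."""

    def __init__(self, nd: int = 2):
        self.nd = nd

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        out = x
        for ax in range(2, 2 + self.nd):
            out = np.repeat(out, 2, axis=ax)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c = dout.shape[:2]
        sp = dout.shape[2:]
        shape = (n, c) + sum(((s // 2, 2) for s in sp), ())
        axes = tuple(3 + 2 * i for i in range(self.nd))
        return dout.reshape(shape).sum(axis=axes)


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._in_shape = x.shape
        return x.mean(axis=tuple(range(2, x.ndim)))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        sp = self._in_shape[2:]
        scale = 1.0 / np.prod(sp)
        return np.broadcast_to(
            dout.reshape(dout.shape + (1,) * len(sp)), self._in_shape
        ) * scale


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng=None, name: str = "fc"):
        rng = rng or np.random.default_rng(0)
        w = rng.normal(0.0, np.sqrt(2.0 / in_features), size=(in_features, out_features))
        self.weight = Param(w, f"{name}.weight")
        self.bias = Param(np.zeros(out_features), f"{name}.bias")

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._x = x
        w = self.weight.value.astype(x.dtype, copy=False)
        return x @ w + self.bias.value.astype(x.dtype, copy=False)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.weight.grad += self._x.T @ dout
        self.bias.grad += dout.sum(axis=0)
        return dout @ self.weight.value.T.astype(dout.dtype, copy=False)


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def dice_loss_and_grad(
    logits: np.ndarray, targets: np.ndarray, smooth: float = 1.0
) -> tuple[float, np.ndarray]:
    """Soft Dice loss over the whole batch: 1 - (2*sum(p*t)+s)/(sum(p)+sum(t)+s).

    Returns the loss and its gradient with respect to the logits.
    """
    p = sigmoid(logits)
    t = np.asarray(targets, dtype=np.float64)
    a = 2.0 * (p * t).sum() + smooth
    b = p.sum() + t.sum() + smooth
    loss = 1.0 - a / b
    dp = -(2.0 * t * b - a) / b**2
    return float(loss), dp * p * (1.0 - p)


def softmax_cross_entropy_and_grad(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch; labels are integer class indices."""
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    eps = 1e-12
    loss = -np.log(p[np.arange(n), labels] + eps).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return float(loss), dlogits / n


# ---------------------------------------------------------------------------
# Optimiser and state utilities
# ---------------------------------------------------------------------------

class Adam:
    def __init__(
        self,
        params: Iterable[Param],
        lr: float = 1e-5,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in self.params]
        self._v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self._m, self._v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def collect_params(layers: Sequence[Layer]) -> list[Param]:
    out: list[Param] = []
    for layer in layers:
        out.extend(layer.params())
    return out


def state_dict(params: Sequence[Param]) -> dict[str, np.ndarray]:
    out = {}
    for i, p in enumerate(params):
        out[f"{i:04d}:{p.name}"] = p.value.copy()
    return out


def load_state_dict(params: Sequence[Param], state: dict[str, np.ndarray]) -> None:
    if len(state) != len(params):
        raise ValueError(
            f"state has {len(state)} tensors, model has {len(params)} parameters"
        )
    for i, p in enumerate(params):
        key = f"{i:04d}:{p.name}"
        if key not in state:
            raise KeyError(f"missing tensor {key!r} in checkpoint")
        if state[key].shape != p.value.shape:
            raise ValueError(
                f"shape mismatch for {key!r}: {state[key].shape} vs {p.value.shape}"
            )
        p.value = state[key].astype(np.float64).copy()


def bn_state(layers: Sequence[Layer]) -> dict[str, np.ndarray]:
    """Running-statistics buffers of every BatchNorm, in layer order."""
    out = {}
    i = 0
    for layer in layers:
        if isinstance(layer, BatchNorm):
            out[f"bn{i:04d}.running_mean"] = layer.running_mean.copy()
            out[f"bn{i:04d}.running_var"] = layer.running_var.copy()
            i += 1
    return out


def load_bn_state(layers: Sequence[Layer], state: dict[str, np.ndarray]) -> None:
    i = 0
    for layer in layers:
        if isinstance(layer, BatchNorm):
            layer.running_mean = state[f"bn{i:04d}.running_mean"].copy()
            layer.running_var = state[f"bn{i:04d}.running_var"].copy()
            i += 1


def state_hash(params: Sequence[Param]) -> str:
    """SHA-256 digest of all parameter tensors (frozen-model contract checks)."""
    h = hashlib.sha256()
    for p in params:
        h.update(np.ascontiguousarray(p.value).tobytes())
    return h.hexdigest()
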