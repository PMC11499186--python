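"""Minimal 3D convolutional network primitives on numpy.

Implements exactly the layer set needed for the age-regression model:
3x3x3 same-padding convolution, batch normalization, 2x2x2 max pooling,
ReLU, 1x1x1 convolution, global average pooling, dropout, and a linear
head, each with an explicit backward pass (including gradients with
respect to the *input*, required for gradient-based saliency).

Tensors are laid out ``(N, C, D, H, W)``. All layers cache what they
need for the backward pass on ``forward(..., train=True)``; inference
calls with ``train=False`` use running statistics (batch norm) and
disable dropout, so predictions are deterministic and independent of
batch composition.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Layer",
    "Conv3d",
    "PointwiseConv3d",
    "BatchNorm3d",
    "MaxPool3d",
    "ReLU",
    "GlobalAvgPool3d",
    "Dropout",
    "Linear",
    "Sequential",
    "Adam",
]


class Param:
    """A trainable tensor together with its accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = value
        self.grad = np.zeros_like(value)
        self.name = name


class Layer:
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int,
             dtype: np.dtype) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


class Conv3d(Layer):
    """3x3x3 convolution, stride 1, zero 'same' padding, via im2col."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator,
                 kernel: int = 3, dtype: np.dtype = np.float32) -> None:
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        self.k = kernel
        self.in_ch = in_ch
        self.out_ch = out_ch
        fan_in = in_ch * kernel ** 3
        self.W = Param(_he_init(rng, (out_ch, in_ch) + (kernel,) * 3, fan_in,
                                dtype), "conv.W")
        self.b = Param(np.zeros(out_ch, dtype=dtype), "conv.b")
        self._cols: np.ndarray | None = None
        self._xshape: tuple[int, ...] | None = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        k, p = self.k, self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0)) + ((p, p),) * 3)
        # (N, C, D, H, W, k, k, k) view -> (N*D*H*W, C*k^3) copy
        win = sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))
        n, c, d, h, w = x.shape
        cols = win.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(
            n * d * h * w, c * k ** 3)
        return np.ascontiguousarray(cols)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, d, h, w = x.shape
        cols = self._im2col(x)
        Wm = self.W.value.reshape(self.out_ch, -1)
        out = cols @ Wm.T
        out += self.b.value
        # cols are only needed for the weight gradient; input gradients
        # (saliency) work without them.
        self._cols = cols if train else None
        self._xshape = x.shape
        return out.reshape(n, d, h, w, self.out_ch).transpose(0, 4, 1, 2, 3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, f, d, h, w = dout.shape
        k, p = self.k, self.k // 2
        dmat = dout.transpose(0, 2, 3, 4, 1).reshape(-1, f)
        Wm = self.W.value.reshape(f, -1)
        if self._cols is not None:
            self.W.grad += (dmat.T @ self._cols).reshape(self.W.value.shape)
            self.b.grad += dmat.sum(axis=0)
        dcols = dmat @ Wm  # (N*D*H*W, C*k^3)
        dcols = dcols.reshape(n, d, h, w, self.in_ch, k, k, k)
        dxp = np.zeros((n, self.in_ch, d + 2 * p, h + 2 * p, w + 2 * p),
                       dtype=dout.dtype)
        for i in range(k):
            for j in range(k):
                for l in range(k):
                    dxp[:, :, i:i + d, j:j + h, l:l + w] += \
                        dcols[:, :, :, :, :, i, j, l].transpose(0, 4, 1, 2, 3)
        self._cols = None
        return dxp[:, :, p:p + d, p:p + h, p:p + w]


class PointwiseConv3d(Layer):
    """1x1x1 convolution: a per-voxel linear map over channels."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator,
                 dtype: np.dtype = np.float32) -> None:
        self.in_ch = in_ch
        self.out_ch = out_ch
        self.W = Param(_he_init(rng, (out_ch, in_ch), in_ch, dtype), "pw.W")
        self.b = Param(np.zeros(out_ch, dtype=dtype), "pw.b")
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x if train else None
        out = np.einsum("ncdhw,fc->nfdhw", x, self.W.value, optimize=True)
        return out + self.b.value[None, :, None, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._x is not None:
            self.W.grad += np.einsum("nfdhw,ncdhw->fc", dout, self._x,
                                     optimize=True)
            self.b.grad += dout.sum(axis=(0, 2, 3, 4))
            self._x = None
        return np.einsum("nfdhw,fc->ncdhw", dout, self.W.value, optimize=True)


class BatchNorm3d(Layer):
    """Per-channel batch normalization over (N, D, H, W).

    Uses batch statistics in training and running statistics at
    inference, so inference output for a volume does not depend on the
    rest of the batch.
    """

    def __init__(self, n_ch: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype: np.dtype = np.float32) -> None:
        self.eps = eps
        self.momentum = momentum
        self.gamma = Param(np.ones(n_ch, dtype=dtype), "bn.gamma")
        self.beta = Param(np.zeros(n_ch, dtype=dtype), "bn.beta")
        self.running_mean = np.zeros(n_ch, dtype=dtype)
        self.running_var = np.ones(n_ch, dtype=dtype)
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        axes = (0, 2, 3, 4)
        shape = (1, -1, 1, 1, 1)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean
                                 + m * mean).astype(self.running_mean.dtype)
            self.running_var = ((1 - m) * self.running_var
                                + m * var).astype(self.running_var.dtype)
        else:
            mean = self.running_mean
            var = self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(shape)) * inv_std.reshape(shape)
        # In eval mode the statistics are constants, so the backward map
        # is a plain per-channel scaling (used by saliency).
        self._cache = (xhat, inv_std) if train else ("eval", inv_std)
        return self.gamma.value.reshape(shape) * xhat \
            + self.beta.value.reshape(shape)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        assert self._cache is not None
        xhat, inv_std = self._cache
        shape = (1, -1, 1, 1, 1)
        if isinstance(xhat, str):  # eval-mode: running stats are constant
            return dout * (self.gamma.value * inv_std).reshape(shape)
        axes = (0, 2, 3, 4)
        m = float(np.prod([dout.shape[a] for a in axes]))
        self.gamma.grad += (dout * xhat).sum(axis=axes)
        self.beta.grad += dout.sum(axis=axes)
        dxhat = dout * self.gamma.value.reshape(shape)
        dx = (inv_std.reshape(shape) / m) * (
            m * dxhat
            - dxhat.sum(axis=axes).reshape(shape)
            - xhat * (dxhat * xhat).sum(axis=axes).reshape(shape)
        )
        self._cache = None
        return dx


class MaxPool3d(Layer):
    """2x2x2 max pooling, stride 2; odd trailing slices are dropped
    (floor semantics, e.g. 81 -> 40)."""

    def __init__(self) -> None:
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, d, h, w = x.shape
        d2, h2, w2 = d // 2, h // 2, w // 2
        xt = x[:, :, :2 * d2, :2 * h2, :2 * w2]
        xr = xt.reshape(n, c, d2, 2, h2, 2, w2, 2) \
               .transpose(0, 1, 2, 4, 6, 3, 5, 7) \
               .reshape(n, c, d2, h2, w2, 8)
        arg = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, arg[..., None], axis=-1)[..., 0]
        self._cache = (x.shape, arg)  # needed in both train and saliency
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        assert self._cache is not None
        xshape, arg = self._cache
        n, c, d, h, w = xshape
        d2, h2, w2 = d // 2, h // 2, w // 2
        dxr = np.zeros((n, c, d2, h2, w2, 8), dtype=dout.dtype)
        np.put_along_axis(dxr, arg[..., None], dout[..., None], axis=-1)
        dxt = dxr.reshape(n, c, d2, h2, w2, 2, 2, 2) \
                 .transpose(0, 1, 2, 5, 3, 6, 4, 7) \
                 .reshape(n, c, 2 * d2, 2 * h2, 2 * w2)
        dx = np.zeros(xshape, dtype=dout.dtype)
        dx[:, :, :2 * d2, :2 * h2, :2 * w2] = dxt
        self._cache = None
        return dx


class ReLU(Layer):
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        mask = x > 0
        self._mask = mask  # kept in eval mode too (saliency backward)
        return x * mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        assert self._mask is not None
        return dout * self._mask


class GlobalAvgPool3d(Layer):
    """Average over all spatial positions -> (N, C)."""

    def __init__(self) -> None:
        self._xshape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._xshape = x.shape
        return x.mean(axis=(2, 3, 4))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        assert self._xshape is not None
        n, c, d, h, w = self._xshape
        scale = 1.0 / (d * h * w)
        return np.broadcast_to(
            dout[:, :, None, None, None] * scale, self._xshape).copy()


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        self._mask = mask
        return x * mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        return dout * self._mask


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator,
                 dtype: np.dtype = np.float32) -> None:
        self.W = Param(_he_init(rng, (out_features, in_features), in_features,
                                dtype), "linear.W")
        self.b = Param(np.zeros(out_features, dtype=dtype), "linear.b")
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.W.value.T + self.b.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        assert self._x is not None
        self.W.grad += dout.T @ self._x
        self.b.grad += dout.sum(axis=0)
        dx = dout @ self.W.value
        self._x = None
        return dx


class Sequential(Layer):
    def __init__(self, layers: Sequence[Layer]) -> None:
        self.layers = list(layers)

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.layers):
            for j, p in enumerate(layer.params()):
                state[f"layer{i}.param{j}.{p.name}"] = p.value.copy()
            if isinstance(layer, BatchNorm3d):
                state[f"layer{i}.running_mean"] = layer.running_mean.copy()
                state[f"layer{i}.running_var"] = layer.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for j, p in enumerate(layer.params()):
                p.value[...] = state[f"layer{i}.param{j}.{p.name}"]
            if isinstance(layer, BatchNorm3d):
                layer.running_mean[...] = state[f"layer{i}.running_mean"]
                layer.running_var[...] = state[f"layer{i}.running_var"]


class Adam:
    """Adam with L2 weight decay folded into the gradient."""

    def __init__(self, params: Iterable[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0) -> None:
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.value, dtype=np.float64)
                   for p in self.params]
        self._v = [np.zeros_like(p.value, dtype=np.float64)
                   for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad.astype(np.float64)
            if self.weight_decay:
                g = g + self.weight_decay * p.value
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            update = self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
            p.value -= update.astype(p.value.dtype)
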