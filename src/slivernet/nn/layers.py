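"""Minimal neural-network layers on NumPy with explicit backpropagation.

Layers keep forward caches only when ``train=True``; ``backward`` consumes
the cache from the most recent training-mode forward. All parameters are
float32. Convolutions use im2col (``sliding_window_view`` + matmul) with
TensorFlow-style "same" padding, so an input of length L maps to
ceil(L / stride) outputs.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Parameter",
    "Module",
    "Conv2d",
    "Conv1d",
    "Conv3d",
    "Linear",
    "ReLU",
    "MaxPool2d",
    "Sequential",
    "ResidualBlock2d",
    "ResidualBlock3d",
]


class Parameter:
    """A trainable array with an accumulated gradient.

    ``decay`` marks whether weight decay applies (biases opt out).
    """

    __slots__ = ("value", "grad", "decay")

    def __init__(self, value: np.ndarray, decay: bool = True):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.decay = decay

    @property
    def shape(self):
        return self.value.shape

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Module:
    """Base class: recursive parameter discovery and state (de)serialization."""

    def named_parameters(self, prefix: str = ""):
        for name, attr in vars(self).items():
            path = f"{prefix}{name}"
            if isinstance(attr, Parameter):
                yield path, attr
            elif isinstance(attr, Module):
                yield from attr.named_parameters(prefix=path + ".")
            elif isinstance(attr, (list, tuple)):
                for i, item in enumerate(attr):
                    if isinstance(item, Module):
                        yield from item.named_parameters(prefix=f"{path}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def state_dict(self) -> dict:
        return {name: p.value.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict) -> None:
        params = dict(self.named_parameters())
        missing = set(params) - set(state)
        unexpected = set(state) - set(params)
        if missing or unexpected:
            raise ValueError(
                f"state mismatch: missing={sorted(missing)} unexpected={sorted(unexpected)}"
            )
        for name, p in params.items():
            arr = np.asarray(state[name], dtype=np.float32)
            if arr.shape != p.value.shape:
                raise ValueError(
                    f"shape mismatch for {name}: checkpoint {arr.shape} vs model {p.value.shape}"
                )
            p.value = arr.copy()
            p.grad = np.zeros_like(p.value)

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.parameters()))

    def forward(self, x, train: bool = False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - interface
        raise NotImplementedError

    def __call__(self, x, train: bool = False):
        return self.forward(x, train=train)


def _same_pad(size: int, k: int, stride: int) -> tuple[int, int]:
    out = -(-size // stride)  # ceil
    total = max((out - 1) * stride + k - size, 0)
    return total // 2, total - total // 2


def he_init(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Conv2d(Module):
    """2D convolution (cross-correlation), NCHW, "same" padding."""

    def __init__(self, in_ch, out_ch, kernel, stride=1, bias=True, rng=None):
        rng = rng or np.random.default_rng(0)
        self.kh, self.kw = (kernel, kernel) if np.isscalar(kernel) else kernel
        self.stride = stride
        self.in_ch, self.out_ch = in_ch, out_ch
        fan_in = in_ch * self.kh * self.kw
        self.weight = Parameter(he_init(rng, (out_ch, in_ch, self.kh, self.kw), fan_in))
        self.bias = Parameter(np.zeros(out_ch), decay=False) if bias else None
        self._cache = None

    def forward(self, x, train: bool = False):
        n, c, h, w = x.shape
        (pt, pb) = _same_pad(h, self.kh, self.stride)
        (pl, pr) = _same_pad(w, self.kw, self.stride)
        xp = np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
        win = sliding_window_view(xp, (self.kh, self.kw), axis=(2, 3))
        win = win[:, :, :: self.stride, :: self.stride]  # n,c,ho,wo,kh,kw
        ho, wo = win.shape[2], win.shape[3]
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * ho * wo, c * self.kh * self.kw
        )
        wm = self.weight.value.reshape(self.out_ch, -1)
        out = cols @ wm.T
        if self.bias is not None:
            out += self.bias.value
        out = out.reshape(n, ho, wo, self.out_ch).transpose(0, 3, 1, 2)
        if train:
            self._cache = (cols, x.shape, xp.shape, (pt, pl), (ho, wo))
        return np.ascontiguousarray(out)

    def backward(self, dy):
        cols, x_shape, xp_shape, (pt, pl), (ho, wo) = self._cache
        n, c, h, w = x_shape
        dyf = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(-1, self.out_ch)
        self.weight.grad += (dyf.T @ cols).reshape(self.weight.value.shape)
        if self.bias is not None:
            self.bias.grad += dyf.sum(axis=0)
        wm = self.weight.value.reshape(self.out_ch, -1)
        dcols = (dyf @ wm).reshape(n, ho, wo, c, self.kh, self.kw)
        dxp = np.zeros(xp_shape, dtype=np.float32)
        s = self.stride
        for i in range(self.kh):
            for j in range(self.kw):
                dxp[:, :, i : i + s * ho : s, j : j + s * wo : s] += dcols[
                    :, :, :, :, i, j
                ].transpose(0, 3, 1, 2)
        self._cache = None
        return dxp[:, :, pt : pt + h, pl : pl + w]


class Conv1d(Module):
    """1D convolution along the last axis (N, C, L), implemented via Conv2d."""

    def __init__(self, in_ch, out_ch, kernel, stride=1, bias=True, rng=None):
        self.conv = Conv2d(in_ch, out_ch, (1, kernel), stride=stride, bias=bias, rng=rng)

    def forward(self, x, train: bool = False):
        return self.conv.forward(x[:, :, None, :], train=train)[:, :, 0, :]

    def backward(self, dy):
        return self.conv.backward(dy[:, :, None, :])[:, :, 0, :]


class Conv3d(Module):
    """3D convolution, NCDHW, "same" padding; used by the volumetric baseline."""

    def __init__(self, in_ch, out_ch, kernel, stride=1, bias=True, rng=None):
        rng = rng or np.random.default_rng(0)
        self.kd, self.kh, self.kw = (
            (kernel, kernel, kernel) if np.isscalar(kernel) else kernel
        )
        self.stride = stride
        self.in_ch, self.out_ch = in_ch, out_ch
        fan_in = in_ch * self.kd * self.kh * self.kw
        self.weight = Parameter(
            he_init(rng, (out_ch, in_ch, self.kd, self.kh, self.kw), fan_in)
        )
        self.bias = Parameter(np.zeros(out_ch), decay=False) if bias else None
        self._cache = None

    def forward(self, x, train: bool = False):
        n, c, d, h, w = x.shape
        pads = [
            _same_pad(d, self.kd, self.stride),
            _same_pad(h, self.kh, self.stride),
            _same_pad(w, self.kw, self.stride),
        ]
        xp = np.pad(x, ((0, 0), (0, 0), *pads))
        win = sliding_window_view(xp, (self.kd, self.kh, self.kw), axis=(2, 3, 4))
        s = self.stride
        win = win[:, :, ::s, ::s, ::s]
        do, ho, wo = win.shape[2:5]
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 4, 1, 5, 6, 7)).reshape(
            n * do * ho * wo, c * self.kd * self.kh * self.kw
        )
        wm = self.weight.value.reshape(self.out_ch, -1)
        out = cols @ wm.T
        if self.bias is not None:
            out += self.bias.value
        out = out.reshape(n, do, ho, wo, self.out_ch).transpose(0, 4, 1, 2, 3)
        if train:
            self._cache = (cols, x.shape, xp.shape, tuple(p[0] for p in pads), (do, ho, wo))
        return np.ascontiguousarray(out)

    def backward(self, dy):
        cols, x_shape, xp_shape, (pd, pt, pl), (do, ho, wo) = self._cache
        n, c, d, h, w = x_shape
        dyf = np.ascontiguousarray(dy.transpose(0, 2, 3, 4, 1)).reshape(-1, self.out_ch)
        self.weight.grad += (dyf.T @ cols).reshape(self.weight.value.shape)
        if self.bias is not None:
            self.bias.grad += dyf.sum(axis=0)
        wm = self.weight.value.reshape(self.out_ch, -1)
        dcols = (dyf @ wm).reshape(n, do, ho, wo, c, self.kd, self.kh, self.kw)
        dxp = np.zeros(xp_shape, dtype=np.float32)
        s = self.stride
        for a in range(self.kd):
            for i in range(self.kh):
                for j in range(self.kw):
                    dxp[
                        :, :, a : a + s * do : s, i : i + s * ho : s, j : j + s * wo : s
                    ] += dcols[:, :, :, :, :, a, i, j].transpose(0, 4, 1, 2, 3)
        self._cache = None
        return dxp[:, :, pd : pd + d, pt : pt + h, pl : pl + w]


class Linear(Module):
    def __init__(self, in_features, out_features, bias=True, rng=None):
        rng = rng or np.random.default_rng(0)
        self.weight = Parameter(he_init(rng, (out_features, in_features), in_features))
        self.bias = Parameter(np.zeros(out_features), decay=False) if bias else None
        self._cache = None

    def forward(self, x, train: bool = False):
        out = x @ self.weight.value.T
        if self.bias is not None:
            out += self.bias.value
        if train:
            self._cache = x
        return out

    def backward(self, dy):
        x = self._cache
        self.weight.grad += dy.T @ x
        if self.bias is not None:
            self.bias.grad += dy.sum(axis=0)
        self._cache = None
        return dy @ self.weight.value


class ReLU(Module):
    def __init__(self):
        self._mask = None

    def forward(self, x, train: bool = False):
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dy):
        dx = dy * self._mask
        self._mask = None
        return dx


class MaxPool2d(Module):
    """Max pooling with "same" padding (pads with -inf)."""

    def __init__(self, kernel=3, stride=2):
        self.k = kernel
        self.stride = stride
        self._cache = None

    def forward(self, x, train: bool = False):
        n, c, h, w = x.shape
        (pt, pb) = _same_pad(h, self.k, self.stride)
        (pl, pr) = _same_pad(w, self.k, self.stride)
        xp = np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr)), constant_values=-np.inf)
        win = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        win = win[:, :, :: self.stride, :: self.stride]
        ho, wo = win.shape[2], win.shape[3]
        flat = win.reshape(n, c, ho, wo, self.k * self.k)
        idx = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (idx, x.shape, xp.shape, (pt, pl), (ho, wo))
        return np.ascontiguousarray(out)

    def backward(self, dy):
        idx, x_shape, xp_shape, (pt, pl), (ho, wo) = self._cache
        n, c, h, w = x_shape
        dxp = np.zeros(xp_shape, dtype=np.float32)
        ni, ci, hi, wi = np.ogrid[0:n, 0:c, 0:ho, 0:wo]
        rows = hi * self.stride + idx // self.k
        cols = wi * self.stride + idx % self.k
        np.add.at(dxp, (ni, ci, rows, cols), dy)
        self._cache = None
        return dxp[:, :, pt : pt + h, pl : pl + w]


class Sequential(Module):
    def __init__(self, *mods):
        self.mods = list(mods)

    def forward(self, x, train: bool = False):
        for m in self.mods:
            x = m.forward(x, train=train)
        return x

    def backward(self, dy):
        for m in reversed(self.mods):
            dy = m.backward(dy)
        return dy


class ResidualBlock2d(Module):
    """conv3x3(stride)-relu-conv3x3 + shortcut, then relu.

    The shortcut is identity when shapes match, else a strided 1x1 projection.
    Parameter-free otherwise (no normalization layers): at the small model
    scales this package targets, plain He-initialized residual stacks train
    stably and keep forward passes bit-deterministic.
    """

    def __init__(self, in_ch, out_ch, stride=1, rng=None):
        self.conv1 = Conv2d(in_ch, out_ch, 3, stride=stride, rng=rng)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(out_ch, out_ch, 3, stride=1, rng=rng)
        self.proj = (
            Conv2d(in_ch, out_ch, 1, stride=stride, bias=False, rng=rng)
            if (stride != 1 or in_ch != out_ch)
            else None
        )
        self.relu2 = ReLU()

    def forward(self, x, train: bool = False):
        y = self.relu1.forward(self.conv1.forward(x, train), train)
        z = self.conv2.forward(y, train)
        sc = self.proj.forward(x, train) if self.proj is not None else x
        return self.relu2.forward(z + sc, train)

    def backward(self, dy):
        dsum = self.relu2.backward(dy)
        dx = self.conv1.backward(self.relu1.backward(self.conv2.backward(dsum)))
        dx += self.proj.backward(dsum) if self.proj is not None else dsum
        return dx


class ResidualBlock3d(Module):
    """3D analog of ResidualBlock2d (3x3x3 kernels)."""

    def __init__(self, in_ch, out_ch, stride=1, rng=None):
        self.conv1 = Conv3d(in_ch, out_ch, 3, stride=stride, rng=rng)
        self.relu1 = ReLU()
        self.conv2 = Conv3d(out_ch, out_ch, 3, stride=1, rng=rng)
        self.proj = (
            Conv3d(in_ch, out_ch, 1, stride=stride, bias=False, rng=rng)
            if (stride != 1 or in_ch != out_ch)
            else None
        )
        self.relu2 = ReLU()

    def forward(self, x, train: bool = False):
        y = self.relu1.forward(self.conv1.forward(x, train), train)
        z = self.conv2.forward(y, train)
        sc = self.proj.forward(x, train) if self.proj is not None else x
        return self.relu2.forward(z + sc, train)

    def backward(self, dy):
        dsum = self.relu2.backward(dy)
        dx = self.conv1.backward(self.relu1.backward(self.conv2.backward(dsum)))
        dx += self.proj.backward(dsum) if self.proj is not None else dsum
        return dx
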