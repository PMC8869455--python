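"""Minimal numpy neural-network layer framework.

Declarative :class:`NetworkSpec` objects describe layer stacks (dense,
convolution, transposed convolution, activations, dropout, reshape) with
exact shape composition and trainable-parameter arithmetic; ``spec.build``
instantiates a :class:`Network` with initialized weights, manual
forward/backward passes, and Adam updates.

Everything runs single-threaded on CPU arrays.  Image tensors are
channels-last ``(N, H, W, C)``; dense activations are ``(N, units)``.
Convolutions use "same" zero padding, the only mode the builders need.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "LayerSpec",
    "NetworkSpec",
    "Network",
    "Adam",
    "dense",
    "conv2d",
    "conv2d_transpose",
    "reshape",
    "flatten",
    "leaky_relu",
    "relu",
    "sigmoid",
    "tanh",
    "dropout",
    "residual",
]

# ---------------------------------------------------------------------------
# layer descriptors


@dataclass(frozen=True)
class LayerSpec:
    """One layer of a :class:`NetworkSpec`.

    ``kind`` is one of ``dense, conv, transposed-conv, reshape, flatten,
    leaky-relu, relu, sigmoid, tanh, dropout``.  Conv kinds carry
    ``filters`` (output channels), ``kernel``, ``stride``; padding is
    always "same".
    """

    kind: str
    units: Optional[int] = None          # dense
    filters: Optional[int] = None        # conv kinds
    kernel: Optional[int] = None
    stride: int = 1
    shape: Optional[tuple] = None        # reshape target (H, W, C)
    rate: float = 0.0                    # dropout
    slope: float = 0.2                   # leaky-relu
    inner: tuple = ()                    # residual branch layers

    def out_shape(self, in_shape: tuple) -> tuple:
        k = self.kind
        if k == "residual":
            cur = in_shape
            for sub in self.inner:
                cur = sub.out_shape(cur)
            if tuple(cur) != tuple(in_shape):
                raise ValueError(
                    f"residual branch must preserve shape, got {in_shape} -> {cur}")
            return in_shape
        if k == "dense":
            if len(in_shape) != 1:
                raise ValueError(f"dense layer needs a flat input, got {in_shape}")
            return (self.units,)
        if k == "conv":
            h, w, _ = in_shape
            s = self.stride
            return ((h + s - 1) // s, (w + s - 1) // s, self.filters)
        if k == "transposed-conv":
            h, w, _ = in_shape
            return (h * self.stride, w * self.stride, self.filters)
        if k == "reshape":
            if int(np.prod(in_shape)) != int(np.prod(self.shape)):
                raise ValueError(f"cannot reshape {in_shape} to {self.shape}")
            return tuple(self.shape)
        if k == "flatten":
            return (int(np.prod(in_shape)),)
        if k in ("leaky-relu", "relu", "sigmoid", "tanh", "dropout"):
            return in_shape
        raise ValueError(f"unknown layer kind {self.kind!r}")

    def param_count(self, in_shape: tuple) -> int:
        if self.kind == "residual":
            total, cur = 0, in_shape
            for sub in self.inner:
                total += sub.param_count(cur)
                cur = sub.out_shape(cur)
            return total
        if self.kind == "dense":
            return (in_shape[0] + 1) * self.units
        if self.kind in ("conv", "transposed-conv"):
            c_in = in_shape[-1]
            return self.kernel * self.kernel * c_in * self.filters + self.filters
        return 0


def dense(units: int) -> LayerSpec:
    return LayerSpec("dense", units=units)


def conv2d(filters: int, kernel: int, stride: int = 1) -> LayerSpec:
    return LayerSpec("conv", filters=filters, kernel=kernel, stride=stride)


def conv2d_transpose(filters: int, kernel: int, stride: int = 2) -> LayerSpec:
    return LayerSpec("transposed-conv", filters=filters, kernel=kernel, stride=stride)


def reshape(shape: Sequence[int]) -> LayerSpec:
    return LayerSpec("reshape", shape=tuple(shape))


def flatten() -> LayerSpec:
    return LayerSpec("flatten")


def leaky_relu(slope: float = 0.2) -> LayerSpec:
    return LayerSpec("leaky-relu", slope=slope)


def relu() -> LayerSpec:
    return LayerSpec("relu", slope=0.0)


def sigmoid() -> LayerSpec:
    return LayerSpec("sigmoid")


def tanh() -> LayerSpec:
    return LayerSpec("tanh")


def dropout(rate: float) -> LayerSpec:
    return LayerSpec("dropout", rate=rate)


def residual(inner: Sequence[LayerSpec]) -> LayerSpec:
    """Identity-skip block: output = input + branch(input)."""
    return LayerSpec("residual", inner=tuple(inner))


@dataclass
class NetworkSpec:
    """Declarative layer stack with shape and parameter-count arithmetic."""

    input_shape: tuple
    layers: list = field(default_factory=list)
    name: str = "network"

    def shapes(self) -> list:
        """Per-layer output shapes (input excluded)."""
        out = []
        cur = tuple(self.input_shape)
        for layer in self.layers:
            cur = layer.out_shape(cur)
            out.append(cur)
        return out

    @property
    def output_shape(self) -> tuple:
        cur = tuple(self.input_shape)
        for layer in self.layers:
            cur = layer.out_shape(cur)
        return cur

    def param_counts(self) -> list:
        counts = []
        cur = tuple(self.input_shape)
        for layer in self.layers:
            counts.append(layer.param_count(cur))
            cur = layer.out_shape(cur)
        return counts

    @property
    def total_params(self) -> int:
        return int(sum(self.param_counts()))

    def summary(self) -> str:
        lines = [f"{self.name}: input {self.input_shape}"]
        cur = tuple(self.input_shape)
        for layer, n in zip(self.layers, self.param_counts()):
            cur = layer.out_shape(cur)
            lines.append(f"  {layer.kind:<16} {str(cur):<20} {n:>12,d}")
        lines.append(f"  total params: {self.total_params:,d}")
        return "\n".join(lines)

    def build(self, rng: np.random.Generator) -> "Network":
        return Network(self, rng)


# ---------------------------------------------------------------------------
# compute layers

def _im2col(x: np.ndarray, k: int, stride: int, pad: tuple) -> np.ndarray:
    """(N,H,W,C) -> (N*Ho*Wo, k*k*C) patch matrix, zero 'same' padding."""
    n, h, w, c = x.shape
    (pt, pb), (pl, pr) = pad
    xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
    hp, wp = xp.shape[1], xp.shape[2]
    ho = (hp - k) // stride + 1
    wo = (wp - k) // stride + 1
    s0, s1, s2, s3 = xp.strides
    patches = np.lib.stride_tricks.as_strided(
        xp,
        shape=(n, ho, wo, k, k, c),
        strides=(s0, s1 * stride, s2 * stride, s1, s2, s3),
        writeable=False,
    )
    return patches.reshape(n * ho * wo, k * k * c), (n, ho, wo, hp, wp)


def _col2im(cols: np.ndarray, meta, k: int, stride: int, pad: tuple, in_shape) -> np.ndarray:
    """Adjoint of _im2col: scatter-add patch gradients back to the image."""
    n, ho, wo, hp, wp = meta
    _, h, w, c = in_shape
    (pt, _), (pl, _) = pad
    grad = np.zeros((n, hp, wp, c), dtype=cols.dtype)
    cols = cols.reshape(n, ho, wo, k, k, c)
    for i in range(k):
        for j in range(k):
            grad[:, i : i + ho * stride : stride, j : j + wo * stride : stride, :] += cols[:, :, :, i, j, :]
    return grad[:, pt : pt + h, pl : pl + w, :]


def _same_pad(h: int, k: int, stride: int) -> tuple:
    """Keras-style asymmetric 'same' padding along one axis."""
    out = (h + stride - 1) // stride
    total = max((out - 1) * stride + k - h, 0)
    lo = total // 2
    return lo, total - lo


class _Layer:
    params: list
    grads: list

    def __init__(self):
        self.params, self.grads = [], []

    def forward(self, x, train, rng):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, g):  # pragma: no cover - interface
        raise NotImplementedError


class _Dense(_Layer):
    def __init__(self, n_in, n_out, rng):
        super().__init__()
        scale = np.sqrt(2.0 / (n_in + n_out))
        self.W = rng.normal(0.0, scale, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train, rng):
        self._x = x
        return x @ self.W + self.b

    def backward(self, g):
        self.grads[0][...] = self._x.T @ g
        self.grads[1][...] = g.sum(axis=0)
        return g @ self.W.T


class _Conv(_Layer):
    def __init__(self, in_shape, filters, kernel, stride, rng):
        super().__init__()
        c_in = in_shape[-1]
        fan_in = kernel * kernel * c_in
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(kernel, kernel, c_in, filters))
        self.b = np.zeros(filters)
        self.k, self.s = kernel, stride
        self.in_shape = in_shape
        self.pad = (_same_pad(in_shape[0], kernel, stride), _same_pad(in_shape[1], kernel, stride))
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train, rng):
        cols, meta = _im2col(x, self.k, self.s, self.pad)
        self._cols, self._meta, self._n = cols, meta, x.shape[0]
        n, ho, wo = meta[0], meta[1], meta[2]
        out = cols @ self.W.reshape(-1, self.W.shape[-1]) + self.b
        return out.reshape(n, ho, wo, -1)

    def backward(self, g):
        f = g.shape[-1]
        gmat = g.reshape(-1, f)
        self.grads[0][...] = (self._cols.T @ gmat).reshape(self.W.shape)
        self.grads[1][...] = gmat.sum(axis=0)
        gcols = gmat @ self.W.reshape(-1, f).T
        return _col2im(gcols, self._meta, self.k, self.s, self.pad,
                       (self._n,) + tuple(self.in_shape))


class _ConvTranspose(_Layer):
    """Stride-s transposed convolution, the adjoint of a same-padded conv.

    Forward here is implemented as the backward-input pass of a conv whose
    input shape equals this layer's *output* shape, which is exactly the
    Keras Conv2DTranspose("same") arithmetic for out = in * stride.
    """

    def __init__(self, in_shape, filters, kernel, stride, rng):
        super().__init__()
        c_in = in_shape[-1]
        fan_in = kernel * kernel * c_in
        # weight laid out as the adjoint conv's kernel: (k, k, filters, c_in)
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(kernel, kernel, filters, c_in))
        self.b = np.zeros(filters)
        self.k, self.s = kernel, stride
        self.in_shape = in_shape
        self.out_hw = (in_shape[0] * stride, in_shape[1] * stride)
        self.pad = (_same_pad(self.out_hw[0], kernel, stride), _same_pad(self.out_hw[1], kernel, stride))
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train, rng):
        n = x.shape[0]
        self._x = x
        c_in = self.in_shape[-1]
        f = self.W.shape[2]
        gmat = x.reshape(-1, c_in)
        gcols = gmat @ self.W.reshape(-1, c_in).T
        ho, wo = self.in_shape[0], self.in_shape[1]
        hp = self.out_hw[0] + sum(self.pad[0])
        wp = self.out_hw[1] + sum(self.pad[1])
        meta = (n, ho, wo, hp, wp)
        out = _col2im(gcols, meta, self.k, self.s, self.pad,
                      (n,) + (self.out_hw[0], self.out_hw[1], f))
        return out + self.b

    def backward(self, g):
        cols, meta = _im2col(g, self.k, self.s, self.pad)
        c_in = self.in_shape[-1]
        xmat = self._x.reshape(-1, c_in)
        self.grads[0][...] = (cols.T @ xmat).reshape(self.W.shape)
        self.grads[1][...] = g.sum(axis=(0, 1, 2))
        gx = cols @ self.W.reshape(-1, c_in)
        n = g.shape[0]
        return gx.reshape((n,) + tuple(self.in_shape))


class _Reshape(_Layer):
    def __init__(self, in_shape, out_shape):
        super().__init__()
        self.in_shape, self.out_shape = tuple(in_shape), tuple(out_shape)

    def forward(self, x, train, rng):
        return x.reshape((x.shape[0],) + self.out_shape)

    def backward(self, g):
        return g.reshape((g.shape[0],) + self.in_shape)


class _LeakyReLU(_Layer):
    def __init__(self, slope):
        super().__init__()
        self.slope = slope

    def forward(self, x, train, rng):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, g):
        return np.where(self._mask, g, self.slope * g)


class _Sigmoid(_Layer):
    def forward(self, x, train, rng):
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        return self._y

    def backward(self, g):
        return g * self._y * (1.0 - self._y)


class _Tanh(_Layer):
    def forward(self, x, train, rng):
        self._y = np.tanh(x)
        return self._y

    def backward(self, g):
        return g * (1.0 - self._y ** 2)


class _Dropout(_Layer):
    def __init__(self, rate):
        super().__init__()
        self.rate = rate

    def forward(self, x, train, rng):
        if not train or self.rate <= 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("dropout in training mode needs an rng")
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask


class _Residual(_Layer):
    def __init__(self, in_shape, inner_specs, rng):
        super().__init__()
        self._inner = []
        cur = tuple(in_shape)
        for spec in inner_specs:
            self._inner.append(_BUILDERS[spec.kind](spec, cur, rng))
            cur = spec.out_shape(cur)
        self.params = [p for l in self._inner for p in l.params]
        self.grads = [g for l in self._inner for g in l.grads]

    def forward(self, x, train, rng):
        y = x
        for layer in self._inner:
            y = layer.forward(y, train, rng)
        return x + y

    def backward(self, g):
        gb = g
        for layer in reversed(self._inner):
            gb = layer.backward(gb)
        return g + gb


_BUILDERS = {
    "leaky-relu": lambda spec, shp, rng: _LeakyReLU(spec.slope),
    "relu": lambda spec, shp, rng: _LeakyReLU(0.0),
    "sigmoid": lambda spec, shp, rng: _Sigmoid(),
    "tanh": lambda spec, shp, rng: _Tanh(),
    "dropout": lambda spec, shp, rng: _Dropout(spec.rate),
    "flatten": lambda spec, shp, rng: _Reshape(shp, (int(np.prod(shp)),)),
    "reshape": lambda spec, shp, rng: _Reshape(shp, spec.shape),
    "dense": lambda spec, shp, rng: _Dense(shp[0], spec.units, rng),
    "conv": lambda spec, shp, rng: _Conv(shp, spec.filters, spec.kernel, spec.stride, rng),
    "transposed-conv": lambda spec, shp, rng: _ConvTranspose(shp, spec.filters, spec.kernel, spec.stride, rng),
    "residual": lambda spec, shp, rng: _Residual(shp, spec.inner, rng),
}


class Network:
    """A built, trainable network: forward, backward, flat parameter access."""

    def __init__(self, spec: NetworkSpec, rng: np.random.Generator):
        self.spec = spec
        self._layers = []
        cur = tuple(spec.input_shape)
        for lspec in spec.layers:
            self._layers.append(_BUILDERS[lspec.kind](lspec, cur, rng))
            cur = lspec.out_shape(cur)

    def forward(self, x: np.ndarray, train: bool = False,
                rng: Optional[np.random.Generator] = None) -> np.ndarray:
        for layer in self._layers:
            x = layer.forward(x, train, rng)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self._layers):
            grad = layer.backward(grad)
        return grad

    @property
    def params(self) -> list:
        return [p for layer in self._layers for p in layer.params]

    @property
    def grads(self) -> list:
        return [g for layer in self._layers for g in layer.grads]

    def get_weights(self) -> list:
        return [p.copy() for p in self.params]

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        own = self.params
        if len(own) != len(weights):
            raise ValueError("weight list length mismatch")
        for p, w in zip(own, weights):
            if p.shape != w.shape:
                raise ValueError(f"weight shape mismatch: {p.shape} vs {w.shape}")
            p[...] = w


class Adam:
    """Adam updates over an explicit parameter/gradient list."""

    def __init__(self, params: Sequence[np.ndarray], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in self.params]
        self.v = [np.zeros_like(p) for p in self.params]
        self.t = 0

    def step(self, grads: Sequence[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
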