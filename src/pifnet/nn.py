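"""Minimal N-dimensional CNN building blocks with explicit backpropagation.

Layers operate on channel-first batched arrays ``(N, C, *spatial)`` with 2 or
3 spatial dimensions.  Each layer exposes ``forward(x) -> (y, cache)`` and
``backward(dy, cache) -> (dx, grads)`` where ``grads`` maps parameter names
to gradient arrays; a :class:`Network` chains layers, caches activations for
attribution, and serializes weights as named groups.

Convolutions use the deep-learning cross-correlation convention with "same"
zero padding (left pad ``(k-1)//2``, right pad ``k//2`` per axis, so even
kernels are supported).  The fast path is an im2col / matrix-multiply
formulation; a deliberately simple shifted-slice reference lives in
:mod:`pifnet.oracles`.
"""

from __future__ import annotations

from typing import Any

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer",
    "Conv",
    "ReLU",
    "MaxPool",
    "Flatten",
    "Dense",
    "Network",
    "Adam",
    "softmax",
    "cross_entropy",
    "he_init",
]


def he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int,
            dtype=np.float32) -> np.ndarray:
    """He-normal initialization, the standard choice for ReLU networks."""
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


class Layer:
    """Base class; parameter-free layers leave ``params`` empty."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}

    def set_param(self, name: str, value: np.ndarray) -> None:
        if name not in self.params:
            raise KeyError(name)
        value = np.asarray(value)
        if value.shape != self.params[name].shape:
            raise ValueError(f"shape mismatch for parameter {name}")
        self.params[name] = value.astype(self.params[name].dtype)

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, Any]:
        raise NotImplementedError

    def backward(self, dy: np.ndarray, cache: Any
                 ) -> tuple[np.ndarray, dict[str, np.ndarray]]:
        raise NotImplementedError

    def out_shape(self, in_shape: tuple[int, ...]) -> tuple[int, ...]:
        """Output shape (without batch axis) for a given input shape."""
        raise NotImplementedError

    @property
    def n_params(self) -> int:
        return sum(int(p.size) for p in self.params.values())


def _same_pad(kernel: tuple[int, ...]) -> tuple[tuple[int, int], ...]:
    return tuple(((k - 1) // 2, k // 2) for k in kernel)


class Conv(Layer):
    """Cross-correlation with "same" zero padding and optional bias.

    Weights have shape ``(filters_out, in_channels, *kernel_size)``.
    """

    def __init__(self, in_channels: int, filters_out: int,
                 kernel_size: tuple[int, ...], *, bias: bool = True,
                 rng: np.random.Generator | None = None,
                 dtype=np.float32) -> None:
        super().__init__()
        self.in_channels = int(in_channels)
        self.filters_out = int(filters_out)
        self.kernel_size = tuple(int(k) for k in kernel_size)
        if any(k < 1 for k in self.kernel_size):
            raise ValueError(f"kernel size must be positive, got {self.kernel_size}")
        self.use_bias = bool(bias)
        rng = rng if rng is not None else np.random.default_rng(0)
        fan_in = self.in_channels * int(np.prod(self.kernel_size))
        self.params["W"] = he_init(
            rng, (self.filters_out, self.in_channels, *self.kernel_size),
            fan_in, dtype)
        if self.use_bias:
            self.params["b"] = np.zeros(self.filters_out, dtype=dtype)

    def out_shape(self, in_shape):
        c, *spatial = in_shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} channels, got {c}")
        if any(k > s for k, s in zip(self.kernel_size, spatial)):
            raise ValueError(
                f"kernel {self.kernel_size} larger than spatial input {tuple(spatial)}")
        return (self.filters_out, *spatial)

    def _im2col(self, x: np.ndarray,
                pad: tuple[tuple[int, int], ...] | None = None) -> np.ndarray:
        nd = len(self.kernel_size)
        if pad is None:
            pad = _same_pad(self.kernel_size)
        xp = np.pad(x, ((0, 0), (0, 0)) + pad)
        win = sliding_window_view(xp, self.kernel_size,
                                  axis=tuple(range(2, 2 + nd)))
        # win: (N, C, *spatial_out, *k) -> (N, prod(spatial), C*prod(k))
        n = x.shape[0]
        spatial = win.shape[2:2 + nd]
        cols = np.moveaxis(win, 1, 1 + nd)  # (N, *spatial, C, *k)
        return np.ascontiguousarray(cols).reshape(
            n, int(np.prod(spatial)), -1)

    def forward(self, x):
        self.out_shape(x.shape[1:])  # validate
        nd = len(self.kernel_size)
        spatial = x.shape[2:]
        w = self.params["W"]
        cols = self._im2col(x.astype(w.dtype, copy=False))
        wmat = w.reshape(self.filters_out, -1)
        out = cols @ wmat.T  # (N, prod(spatial), F)
        if self.use_bias:
            out += self.params["b"]
        out = np.moveaxis(out, -1, 1).reshape(x.shape[0], self.filters_out, *spatial)
        return out, (cols, x)

    def input_grad(self, dy: np.ndarray, *, weights: np.ndarray | None = None
                   ) -> np.ndarray:
        """Gradient of the output w.r.t. the input.

        Computed as the transposed convolution: a correlation of ``dy``
        (treated as an ``filters_out``-channel map) with the spatially
        flipped, channel-transposed kernel at mirrored padding.  Independent
        of the input values; ``weights`` defaults to the layer's own kernel
        (LRP reuses this with sign-clipped kernels).
        """
        w = self.params["W"] if weights is None else weights
        nd = len(self.kernel_size)
        n = dy.shape[0]
        spatial = dy.shape[2:]
        wt = np.flip(w, axis=tuple(range(2, 2 + nd)))  # (F, C, *k)
        wt = np.ascontiguousarray(np.moveaxis(wt, 0, 1))  # (C, F, *k)
        pad = tuple((k // 2, (k - 1) // 2) for k in self.kernel_size)
        cols = self._im2col(dy.astype(w.dtype, copy=False), pad)
        out = cols @ wt.reshape(self.in_channels, -1).T  # (N, P, C)
        return np.moveaxis(out, -1, 1).reshape(n, self.in_channels, *spatial)

    def param_grads(self, dy, cache) -> dict[str, np.ndarray]:
        cols, x = cache
        nd = len(self.kernel_size)
        n = x.shape[0]
        w = self.params["W"]
        dmat = dy.reshape(n, self.filters_out, -1).transpose(0, 2, 1)
        dflat = np.ascontiguousarray(dmat).reshape(-1, self.filters_out)
        grads = {"W": (dflat.T @ cols.reshape(dflat.shape[0], -1)).reshape(w.shape)}
        if self.use_bias:
            grads["b"] = dy.sum(axis=(0, *range(2, 2 + nd)))
        return grads

    def backward(self, dy, cache):
        return self.input_grad(dy), self.param_grads(dy, cache)


class ReLU(Layer):
    def forward(self, x):
        mask = x > 0
        return x * mask, mask

    def backward(self, dy, cache):
        return dy * cache, {}

    def out_shape(self, in_shape):
        return tuple(in_shape)


class MaxPool(Layer):
    """Max pooling, stride = window, floor mode (trailing remainders dropped)."""

    def __init__(self, window: tuple[int, ...]) -> None:
        super().__init__()
        self.window = tuple(int(w) for w in window)

    def out_shape(self, in_shape):
        c, *spatial = in_shape
        out_sp = tuple(s // w for s, w in zip(spatial, self.window))
        if any(o < 1 for o in out_sp):
            raise ValueError(
                f"spatial input {tuple(spatial)} too small for pooling "
                f"window {self.window}")
        return (c, *out_sp)

    def _blocks(self, x):
        n, c, *spatial = x.shape
        out_sp = [s // w for s, w in zip(spatial, self.window)]
        crop = tuple(slice(0, o * w) for o, w in zip(out_sp, self.window))
        xc = x[(slice(None), slice(None)) + crop]
        # interleave (o, w) pairs, then bring the w axes to the back
        shape = [n, c]
        for o, w in zip(out_sp, self.window):
            shape += [o, w]
        xb = xc.reshape(shape)
        nd = len(spatial)
        order = [0, 1] + [2 + 2 * i for i in range(nd)] + [3 + 2 * i for i in range(nd)]
        xb = xb.transpose(order).reshape(n, c, *out_sp, -1)
        return xb, out_sp

    def forward(self, x):
        self.out_shape(x.shape[1:])
        xb, out_sp = self._blocks(x)
        arg = xb.argmax(axis=-1)
        out = np.take_along_axis(xb, arg[..., None], axis=-1)[..., 0]
        return out, (arg, x.shape)

    def switches(self, x: np.ndarray) -> np.ndarray:
        """Flat within-window argmax indices (used for winner-takes-all LRP)."""
        xb, _ = self._blocks(x)
        return xb.argmax(axis=-1)

    def _scatter(self, dy, arg, x_shape):
        n, c, *spatial = x_shape
        nd = len(spatial)
        out_sp = [s // w for s, w in zip(spatial, self.window)]
        db = np.zeros((n, c, *out_sp, int(np.prod(self.window))), dtype=dy.dtype)
        np.put_along_axis(db, arg[..., None], dy[..., None], axis=-1)
        db = db.reshape(n, c, *out_sp, *self.window)
        order = [0, 1]
        for i in range(nd):
            order += [2 + i, 2 + nd + i]
        db = db.transpose(order).reshape(
            n, c, *(o * w for o, w in zip(out_sp, self.window)))
        dx = np.zeros(x_shape, dtype=dy.dtype)
        crop = tuple(slice(0, o * w) for o, w in zip(out_sp, self.window))
        dx[(slice(None), slice(None)) + crop] = db
        return dx

    def backward(self, dy, cache):
        arg, x_shape = cache
        return self._scatter(dy, arg, x_shape), {}


class Flatten(Layer):
    def forward(self, x):
        return x.reshape(x.shape[0], -1), x.shape

    def backward(self, dy, cache):
        return dy.reshape(cache), {}

    def out_shape(self, in_shape):
        return (int(np.prod(in_shape)),)


class Dense(Layer):
    """Fully connected layer; weights ``(units, in_features)``."""

    def __init__(self, in_features: int, units: int, *, bias: bool = True,
                 rng: np.random.Generator | None = None,
                 dtype=np.float32) -> None:
        super().__init__()
        self.in_features = int(in_features)
        self.units = int(units)
        self.use_bias = bool(bias)
        rng = rng if rng is not None else np.random.default_rng(0)
        self.params["W"] = he_init(rng, (self.units, self.in_features),
                                   self.in_features, dtype)
        if self.use_bias:
            self.params["b"] = np.zeros(self.units, dtype=dtype)

    def out_shape(self, in_shape):
        if in_shape != (self.in_features,):
            raise ValueError(
                f"expected flat input of {self.in_features}, got {in_shape}")
        return (self.units,)

    def forward(self, x):
        x = x.astype(self.params["W"].dtype, copy=False)
        out = x @ self.params["W"].T
        if self.use_bias:
            out += self.params["b"]
        return out, x

    def param_grads(self, dy, cache) -> dict[str, np.ndarray]:
        grads = {"W": dy.T @ cache}
        if self.use_bias:
            grads["b"] = dy.sum(axis=0)
        return grads

    def backward(self, dy, cache):
        return dy @ self.params["W"], self.param_grads(dy, cache)


class Network:
    """An ordered chain of named layers with a shared parameter namespace."""

    def __init__(self, layers: list[tuple[str, Layer]]) -> None:
        names = [n for n, _ in layers]
        if len(set(names)) != len(names):
            raise ValueError("layer names must be unique")
        self.layers = list(layers)

    def __iter__(self):
        return iter(self.layers)

    def layer(self, name: str) -> Layer:
        for n, l in self.layers:
            if n == name:
                return l
        raise KeyError(name)

    def layer_names(self) -> list[str]:
        return [n for n, _ in self.layers]

    def forward(self, x: np.ndarray, *, with_caches: bool = False):
        """Run the chain; optionally return per-layer inputs and caches.

        When ``with_caches`` is true the return value is
        ``(y, inputs, caches)`` where ``inputs[i]`` is the array fed to layer
        ``i`` (``inputs[-1]`` appended as the final output) and ``caches[i]``
        the layer's backward cache.
        """
        inputs, caches = [], []
        for _, layer in self.layers:
            inputs.append(x)
            x, cache = layer.forward(x)
            caches.append(cache)
        inputs.append(x)
        if with_caches:
            return x, inputs, caches
        return x

    def backward(self, dy: np.ndarray, caches: list, *,
                 input_grad: bool = False
                 ) -> tuple[np.ndarray | None, dict[str, np.ndarray]]:
        """Backpropagate; the gradient w.r.t. the network input is only
        computed when ``input_grad`` is requested (training never needs it).
        """
        grads: dict[str, np.ndarray] = {}
        for i in range(len(self.layers) - 1, -1, -1):
            name, layer = self.layers[i]
            if i == 0 and not input_grad and isinstance(layer, (Conv, Dense)):
                g = layer.param_grads(dy, caches[i])
                dy = None
            else:
                dy, g = layer.backward(dy, caches[i])
            for k, v in g.items():
                grads[f"{name}/{k}"] = v
        return dy, grads

    # -- parameter bookkeeping -------------------------------------------
    def named_params(self) -> dict[str, np.ndarray]:
        out = {}
        for name, layer in self.layers:
            for k, v in layer.params.items():
                out[f"{name}/{k}"] = v
        return out

    @property
    def n_params(self) -> int:
        return sum(l.n_params for _, l in self.layers)

    def set_params(self, values: dict[str, np.ndarray]) -> None:
        current = self.named_params()
        if set(values) != set(current):
            missing = set(current) ^ set(values)
            raise ValueError(f"parameter name mismatch: {sorted(missing)[:5]}")
        for name, layer in self.layers:
            for k in list(layer.params):
                layer.set_param(k, values[f"{name}/{k}"])

    def save(self, path) -> None:
        np.savez(path, **{k.replace("/", "__"): v
                          for k, v in self.named_params().items()})

    def load(self, path) -> None:
        with np.load(path) as npz:
            self.set_params({k.replace("__", "/"): npz[k] for k in npz.files})


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray
                  ) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and its gradient with respect to the logits."""
    p = softmax(logits.astype(np.float64))
    n = logits.shape[0]
    eps = 1e-12
    loss = float(-np.log(p[np.arange(n), labels] + eps).mean())
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return loss, (dlogits / n).astype(logits.dtype)


class Adam:
    """Adam optimizer over a network's named parameters."""

    def __init__(self, net: Network, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.net = net
        self.lr = float(lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        params = net.named_params()
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        params = self.net.named_params()
        for k, g in grads.items():
            g = g.astype(self.m[k].dtype, copy=False)
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            params[k] -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(
                params[k].dtype)
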