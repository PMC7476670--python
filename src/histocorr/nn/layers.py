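"""Minimal CPU neural-network layers with explicit forward/backward passes.

All layers operate on float32 arrays in NCHW layout. Every layer caches what
its backward pass needs during forward; ``backward`` consumes the gradient of
the loss w.r.t. the layer output and returns the gradient w.r.t. its input,
accumulating parameter gradients in ``Parameter.grad``.

Correctness of every analytic gradient is pinned by finite-difference checks
in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Parameter",
    "Module",
    "Chain",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2d",
    "GlobalAvgPool",
    "Flatten",
    "Linear",
    "UpsampleNearest2x",
    "get_state",
    "set_state",
]


class Parameter:
    """A trainable tensor with an accumulated gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.ascontiguousarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)


class Module:
    """Base class: parameter/buffer discovery by attribute walking."""

    def named_parameters(self, prefix: str = ""):
        for key, val in vars(self).items():
            name = f"{prefix}{key}"
            if isinstance(val, Parameter):
                yield name, val
            elif isinstance(val, Module):
                yield from val.named_parameters(prefix=name + ".")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(prefix=f"{name}.{i}.")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = ""):
        buffers = getattr(self, "_buffer_names", ())
        for key in buffers:
            yield f"{prefix}{key}", self
        for key, val in vars(self).items():
            name = f"{prefix}{key}"
            if isinstance(val, Module):
                yield from val.named_buffers(prefix=name + ".")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_buffers(prefix=f"{name}.{i}.")

    def zero_grad(self):
        for p in self.parameters():
            p.grad[...] = 0.0

    def forward(self, x, train: bool = True):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - interface
        raise NotImplementedError

    def __call__(self, x, train: bool = True):
        return self.forward(x, train=train)


class Chain(Module):
    """Sequential composition of modules."""

    def __init__(self, *modules: Module):
        self.modules = list(modules)

    def forward(self, x, train: bool = True):
        for m in self.modules:
            x = m.forward(x, train=train)
        return x

    def backward(self, dout):
        for m in reversed(self.modules):
            dout = m.backward(dout)
        return dout


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    view = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    view = view[:, :, ::stride, ::stride]
    n, c, ho, wo = view.shape[:4]
    col = np.ascontiguousarray(view.transpose(0, 2, 3, 1, 4, 5))
    return col.reshape(n * ho * wo, c * k * k), ho, wo


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, k: int, stride: int = 1,
                 pad: int = 0, bias: bool = True, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * k * k
        # He initialization, appropriate for ReLU nonlinearities
        std = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(rng.normal(0.0, std, size=(out_ch, in_ch, k, k)))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None
        self.in_ch, self.out_ch, self.k, self.stride, self.pad = in_ch, out_ch, k, stride, pad
        self._cache = None

    def forward(self, x, train: bool = True):
        x = np.ascontiguousarray(x, dtype=np.float32)
        col, ho, wo = _im2col(x, self.k, self.stride, self.pad)
        w_mat = self.weight.data.reshape(self.out_ch, -1).T
        out = col @ w_mat
        if self.bias is not None:
            out += self.bias.data
        n = x.shape[0]
        self._cache = (col, x.shape, ho, wo)
        return out.reshape(n, ho, wo, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, dout):
        col, x_shape, ho, wo = self._cache
        n, c, h, w = x_shape
        k, s, p = self.k, self.stride, self.pad
        dmat = np.ascontiguousarray(dout.transpose(0, 2, 3, 1)).reshape(-1, self.out_ch)
        self.weight.grad += (col.T @ dmat).T.reshape(self.weight.data.shape)
        if self.bias is not None:
            self.bias.grad += dmat.sum(axis=0)
        dcol = (dmat @ self.weight.data.reshape(self.out_ch, -1)).reshape(n, ho, wo, c, k, k)
        dx_pad = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=np.float32)
        for ki in range(k):
            for kj in range(k):
                dx_pad[:, :, ki:ki + s * ho:s, kj:kj + s * wo:s] += \
                    dcol[:, :, :, :, ki, kj].transpose(0, 3, 1, 2)
        if p:
            return dx_pad[:, :, p:-p, p:-p]
        return dx_pad


class BatchNorm2d(Module):
    _buffer_names = ("running_mean", "running_var")

    def __init__(self, ch: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(ch))
        self.beta = Parameter(np.zeros(ch))
        self.running_mean = np.zeros(ch, dtype=np.float32)
        self.running_var = np.ones(ch, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def forward(self, x, train: bool = True):
        x = x.astype(np.float32, copy=False)
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(np.float32)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        out = self.gamma.data[None, :, None, None] * xhat + self.beta.data[None, :, None, None]
        self._cache = (xhat.astype(np.float32), inv_std.astype(np.float32), train)
        return out.astype(np.float32)

    def backward(self, dout):
        xhat, inv_std, was_train = self._cache
        self.beta.grad += dout.sum(axis=(0, 2, 3))
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2, 3))
        dxhat = dout * self.gamma.data[None, :, None, None]
        if not was_train:
            return dxhat * inv_std[None, :, None, None]
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        sum_dxhat = dxhat.sum(axis=(0, 2, 3))[None, :, None, None]
        sum_dxhat_xhat = (dxhat * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        dx = (inv_std[None, :, None, None] / m) * (m * dxhat - sum_dxhat - xhat * sum_dxhat_xhat)
        return dx.astype(np.float32)


class ReLU(Module):
    def forward(self, x, train: bool = True):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, dout):
        return np.where(self._mask, dout, 0.0).astype(np.float32)


class MaxPool2d(Module):
    """2x2 max pooling with stride 2; input spatial dims must be even."""

    def forward(self, x, train: bool = True):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"MaxPool2d requires even spatial dims, got {h}x{w}")
        win = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        win = win.reshape(n, c, h // 2, w // 2, 4)
        self._arg = win.argmax(axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(win, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        n, c, h, w = self._in_shape
        dwin = np.zeros((n, c, h // 2, w // 2, 4), dtype=np.float32)
        np.put_along_axis(dwin, self._arg[..., None], dout[..., None], axis=-1)
        dx = dwin.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return np.ascontiguousarray(dx.reshape(n, c, h, w))


class GlobalAvgPool(Module):
    def forward(self, x, train: bool = True):
        self._in_shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        n, c, h, w = self._in_shape
        return np.broadcast_to(dout[:, :, None, None] / (h * w), self._in_shape).astype(np.float32)


class Flatten(Module):
    def forward(self, x, train: bool = True):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._in_shape)


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / in_f)
        self.weight = Parameter(rng.normal(0.0, std, size=(out_f, in_f)))
        self.bias = Parameter(np.zeros(out_f))

    def forward(self, x, train: bool = True):
        self._x = x.astype(np.float32, copy=False)
        return self._x @ self.weight.data.T + self.bias.data

    def backward(self, dout):
        self.weight.grad += dout.T @ self._x
        self.bias.grad += dout.sum(axis=0)
        return (dout @ self.weight.data).astype(np.float32)


class UpsampleNearest2x(Module):
    def forward(self, x, train: bool = True):
        self._in_shape = x.shape
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, dout):
        n, c, h, w = self._in_shape
        return dout.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)).astype(np.float32)


def get_state(module: Module) -> dict[str, np.ndarray]:
    """Snapshot parameters and batchnorm running statistics (deep copies)."""
    state = {name: p.data.copy() for name, p in module.named_parameters()}
    for name, owner in module.named_buffers():
        attr = name.rsplit(".", 1)[-1] if "." in name else name
        state["buffer:" + name] = getattr(owner, attr).copy()
    return state


def set_state(module: Module, state: dict[str, np.ndarray]) -> None:
    params = dict(module.named_parameters())
    for name, arr in state.items():
        if name.startswith("buffer:"):
            bname = name[len("buffer:"):]
            owners = dict(module.named_buffers())
            owner = owners[bname]
            attr = bname.rsplit(".", 1)[-1] if "." in bname else bname
            setattr(owner, attr, arr.copy())
        else:
            params[name].data[...] = arr
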