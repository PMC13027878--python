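"""NCHW layers with analytic backprop.

Convolutions are evaluated as matrix products on im2col patches; the
transposed convolution is the exact adjoint (col2im of the projected input),
so a stride-2/kernel-4/padding-1 stage doubles the spatial size exactly.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from srcorrect.errors import ShapeError


class Parameter:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = data
        self.grad: np.ndarray | None = None

    @property
    def shape(self):
        return self.data.shape


class Module:
    """Base class: recursive parameter/module discovery over attributes."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.forward(x, train=train)

    def named_children(self):
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def modules(self):
        yield self
        for _, child in self.named_children():
            yield from child.modules()

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                yield prefix + name, val
        for name, child in self.named_children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for name in getattr(self, "_buffers", ()):
            yield prefix + name, getattr(self, name)
        for name, child in self.named_children():
            yield from child.named_buffers(prefix + name + ".")

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({name: b.copy() for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        for name, p in own.items():
            if name not in state:
                raise KeyError(f"missing parameter {name!r} in state dict")
            if p.data.shape != state[name].shape:
                raise ShapeError(f"shape mismatch for {name!r}")
            p.data = state[name].astype(p.data.dtype, copy=True)
        bufs = {name for name, _ in self.named_buffers()}
        for name in bufs:
            if name in state:
                self._set_buffer(name, state[name])

    def _set_buffer(self, dotted: str, value: np.ndarray) -> None:
        obj: Module = self
        parts = dotted.split(".")
        for part in parts[:-1]:
            obj = obj[int(part)] if part.isdigit() else getattr(obj, part)
        setattr(obj, parts[-1], value.copy())


# ---------------------------------------------------------------------------
# im2col / col2im

def im2col(x: np.ndarray, k: int, stride: int, pad: int):
    """Extract k×k patches: (B, C, H, W) -> (B, Ho*Wo, C*k*k)."""
    b, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(b, ho * wo, c * k * k)
    return cols, ho, wo


def col2im(cols: np.ndarray, out_shape, k: int, stride: int, pad: int,
           hw_windows: tuple[int, int]) -> np.ndarray:
    """Adjoint of :func:`im2col`: scatter-add patches back onto the canvas."""
    b, c, h, w = out_shape
    hwin, wwin = hw_windows
    canvas = np.zeros((b, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    c6 = cols.reshape(b, hwin, wwin, c, k, k).transpose(0, 3, 1, 2, 4, 5)
    for i in range(k):
        for j in range(k):
            canvas[:, :, i:i + stride * hwin:stride, j:j + stride * wwin:stride] += c6[..., i, j]
    if pad:
        canvas = canvas[:, :, pad:pad + h, pad:pad + w]
    return canvas


# ---------------------------------------------------------------------------
# layers

class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int, stride: int = 1, pad: int = 0,
                 bias: bool = True, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        std = np.sqrt(2.0 / (cin * k * k))
        self.weight = Parameter((rng.standard_normal((cout, cin * k * k)) * std).astype(np.float32))
        self.bias = Parameter(np.zeros(cout, dtype=np.float32)) if bias else None
        self.cin, self.cout, self.k, self.stride, self.pad = cin, cout, k, stride, pad
        self._ctx = None

    def forward(self, x, train=False):
        if x.shape[1] != self.cin:
            raise ShapeError(f"expected {self.cin} input channels, got {x.shape[1]}")
        cols, ho, wo = im2col(x, self.k, self.stride, self.pad)
        y = cols @ self.weight.data.T
        if self.bias is not None:
            y += self.bias.data
        y = y.transpose(0, 2, 1).reshape(x.shape[0], self.cout, ho, wo)
        self._ctx = (cols, x.shape, ho, wo) if train else None
        return y

    def backward(self, dy):
        cols, x_shape, ho, wo = self._ctx
        b = x_shape[0]
        dyf = dy.reshape(b, self.cout, ho * wo).transpose(0, 2, 1)
        dw = np.einsum("blc,blk->ck", dyf, cols, optimize=True)
        self.weight.grad = dw if self.weight.grad is None else self.weight.grad + dw
        if self.bias is not None:
            db = dyf.sum(axis=(0, 1))
            self.bias.grad = db if self.bias.grad is None else self.bias.grad + db
        dcols = dyf @ self.weight.data
        return col2im(dcols, x_shape, self.k, self.stride, self.pad, (ho, wo))


class ConvTranspose2d(Module):
    """Stride-s transposed convolution; output side = (H-1)*s - 2p + k."""

    def __init__(self, cin: int, cout: int, k: int = 4, stride: int = 2, pad: int = 1,
                 bias: bool = True, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        std = np.sqrt(2.0 / (cin * k * k))
        self.weight = Parameter((rng.standard_normal((cin, cout * k * k)) * std).astype(np.float32))
        self.bias = Parameter(np.zeros(cout, dtype=np.float32)) if bias else None
        self.cin, self.cout, self.k, self.stride, self.pad = cin, cout, k, stride, pad
        self._ctx = None

    def forward(self, x, train=False):
        if x.shape[1] != self.cin:
            raise ShapeError(f"expected {self.cin} input channels, got {x.shape[1]}")
        b, _, h, w = x.shape
        xf = x.reshape(b, self.cin, h * w).transpose(0, 2, 1)
        cols = xf @ self.weight.data
        ho = (h - 1) * self.stride - 2 * self.pad + self.k
        wo = (w - 1) * self.stride - 2 * self.pad + self.k
        y = col2im(cols, (b, self.cout, ho, wo), self.k, self.stride, self.pad, (h, w))
        if self.bias is not None:
            y += self.bias.data[None, :, None, None]
        self._ctx = (xf, (b, h, w)) if train else None
        return y

    def backward(self, dy):
        xf, (b, h, w) = self._ctx
        dcols, _, _ = im2col(dy, self.k, self.stride, self.pad)
        dw = np.einsum("blc,blk->ck", xf, dcols, optimize=True)
        self.weight.grad = dw if self.weight.grad is None else self.weight.grad + dw
        if self.bias is not None:
            db = dy.sum(axis=(0, 2, 3))
            self.bias.grad = db if self.bias.grad is None else self.bias.grad + db
        dxf = dcols @ self.weight.data.T
        return dxf.transpose(0, 2, 1).reshape(b, self.cin, h, w)


class BatchNorm2d(Module):
    """Per-channel batch normalization with running statistics.

    When ``frozen`` is set, running statistics are used even in training
    mode and never updated (gradients still flow to gamma/beta and the
    input) — the small-batch stabilization used for the encoder.
    """

    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Parameter(np.ones(c, dtype=np.float32))
        self.beta = Parameter(np.zeros(c, dtype=np.float32))
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self._buffers = ("running_mean", "running_var")
        self.eps, self.momentum = eps, momentum
        self.frozen = False
        self._ctx = None

    def forward(self, x, train=False):
        if train and not self.frozen:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(np.float32)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(np.float32)
            batch_mode = True
        else:
            mean, var = self.running_mean, self.running_var
            batch_mode = False
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * ivar[None, :, None, None]
        y = self.gamma.data[None, :, None, None] * xhat + self.beta.data[None, :, None, None]
        if train:
            self._ctx = (xhat, ivar, batch_mode)
        return y

    def backward(self, dy):
        xhat, ivar, batch_mode = self._ctx
        dgamma = (dy * xhat).sum(axis=(0, 2, 3))
        dbeta = dy.sum(axis=(0, 2, 3))
        self.gamma.grad = dgamma if self.gamma.grad is None else self.gamma.grad + dgamma
        self.beta.grad = dbeta if self.beta.grad is None else self.beta.grad + dbeta
        g = self.gamma.data[None, :, None, None] * ivar[None, :, None, None]
        if not batch_mode:
            return dy * g
        n = dy.shape[0] * dy.shape[2] * dy.shape[3]
        sum_dy = dy.sum(axis=(0, 2, 3), keepdims=True)
        sum_dy_xhat = (dy * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return g * (dy - sum_dy / n - xhat * sum_dy_xhat / n)


class ReLU(Module):
    def __init__(self):
        self._mask = None

    def forward(self, x, train=False):
        y = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, dy):
        return dy * self._mask


class MaxPool2d(Module):
    def __init__(self, k: int = 3, stride: int = 2, pad: int = 1):
        self.k, self.stride, self.pad = k, stride, pad
        self._ctx = None

    def forward(self, x, train=False):
        b, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad), (self.pad, self.pad)),
                    constant_values=-np.inf)
        win = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))[:, :, ::self.stride, ::self.stride]
        ho, wo = win.shape[2], win.shape[3]
        flat = win.reshape(b, c, ho, wo, self.k * self.k)
        idx = flat.argmax(axis=-1)
        y = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        if train:
            self._ctx = (idx, x.shape, (ho, wo))
        return y

    def backward(self, dy):
        idx, x_shape, (ho, wo) = self._ctx
        b, c, h, w = x_shape
        dxp = np.zeros((b, c, h + 2 * self.pad, w + 2 * self.pad), dtype=dy.dtype)
        bi, ci, hi, wi = np.indices(idx.shape)
        rows = hi * self.stride + idx // self.k
        cols = wi * self.stride + idx % self.k
        np.add.at(dxp, (bi, ci, rows, cols), dy)
        if self.pad:
            dxp = dxp[:, :, self.pad:self.pad + h, self.pad:self.pad + w]
        return dxp


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy
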