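"""Minimal CNN toolkit: layers, losses, Adam, LR scheduling, serialization.

Everything runs on numpy float32 arrays in NCHW layout. The toolkit covers
exactly what the cataract pipeline needs — strided 3x3 convolutions, 4x4/stride-2
transposed convolutions for the autoencoder decoder, depthwise convolutions for
the mobile-style classifiers, batch normalization, pooling, and residual blocks —
with hand-written backward passes (verified against numerical gradients in the
test suite).

Each layer can describe itself as a serializable op dict (``to_ops``) so trained
networks can be exported to the portable graph format and re-executed by an
independent interpreter (see :mod:`nucat.export`).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

F32 = np.float32


class Param:
    """A trainable tensor with its accumulated gradient."""

    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = np.ascontiguousarray(value, dtype=F32)
        self.grad = np.zeros_like(self.value)


class Module:
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []

    # persistent but non-trainable state (e.g. batch-norm running stats)
    def buffers(self) -> list[tuple[str, np.ndarray]]:
        return []

    def to_ops(self) -> list[dict]:
        """Op dicts for the portable graph export; weights referenced by name."""
        raise NotImplementedError

    def __call__(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.forward(x, train=train)


def he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(F32)


class Conv2d(Module):
    """3x3/1x1/7x7 convolution via im2col + matmul; stride s, symmetric padding p."""

    def __init__(self, name: str, c_in: int, c_out: int, k: int, stride: int,
                 pad: int, rng: np.random.Generator, bias: bool = True):
        self.name, self.c_in, self.c_out = name, c_in, c_out
        self.k, self.s, self.p = k, stride, pad
        self.w = Param(f"{name}.w", he_init(rng, (c_out, c_in * k * k), c_in * k * k))
        self.b = Param(f"{name}.b", np.zeros(c_out, F32)) if bias else None
        self._cols = None
        self._xshape = None

    def _out_hw(self, h: int, w: int) -> tuple[int, int]:
        return ((h + 2 * self.p - self.k) // self.s + 1,
                (w + 2 * self.p - self.k) // self.s + 1)

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        if c != self.c_in:
            raise ValueError(f"{self.name}: expected {self.c_in} channels, got {c}")
        ho, wo = self._out_hw(h, w)
        xp = np.pad(x, ((0, 0), (0, 0), (self.p, self.p), (self.p, self.p)))
        win = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))[:, :, ::self.s, ::self.s]
        # (n, c, ho, wo, k, k) -> (n, ho, wo, c*k*k)
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(n, ho, wo, -1)
        if train:
            self._cols, self._xshape = cols, x.shape
        y = cols @ self.w.value.T
        if self.b is not None:
            y += self.b.value
        return np.ascontiguousarray(y.transpose(0, 3, 1, 2))

    def backward(self, gy):
        n, _, ho, wo = gy.shape
        _, c, h, w = self._xshape
        g = np.ascontiguousarray(gy.transpose(0, 2, 3, 1)).reshape(-1, self.c_out)
        cols = self._cols.reshape(-1, self.c_in * self.k * self.k)
        self.w.grad += g.T @ cols
        if self.b is not None:
            self.b.grad += g.sum(axis=0)
        gcols = (g @ self.w.value).reshape(n, ho, wo, self.c_in, self.k, self.k)
        gcols = gcols.transpose(0, 3, 1, 2, 4, 5)  # n, c, ho, wo, k, k
        gxp = np.zeros((n, c, h + 2 * self.p, w + 2 * self.p), F32)
        for i in range(self.k):
            for j in range(self.k):
                gxp[:, :, i:i + self.s * ho:self.s, j:j + self.s * wo:self.s] += gcols[..., i, j]
        self._cols = None
        return gxp[:, :, self.p:self.p + h, self.p:self.p + w]

    def params(self):
        return [self.w] + ([self.b] if self.b is not None else [])

    def to_ops(self):
        op = {"op": "conv2d", "k": self.k, "stride": self.s, "pad": self.p,
              "c_in": self.c_in, "c_out": self.c_out, "weight": self.w.name}
        if self.b is not None:
            op["bias"] = self.b.name
        return [op]


class ConvTranspose2d(Module):
    """Transposed convolution; with k=4, s=2, p=1 it exactly doubles H and W."""

    def __init__(self, name: str, c_in: int, c_out: int, k: int, stride: int,
                 pad: int, rng: np.random.Generator):
        self.name, self.c_in, self.c_out = name, c_in, c_out
        self.k, self.s, self.p = k, stride, pad
        # layout (c_in, c_out*k*k) so forward is one matmul over input pixels
        self.w = Param(f"{name}.w", he_init(rng, (c_in, c_out * k * k), c_in * k * k))
        self.b = Param(f"{name}.b", np.zeros(c_out, F32))
        self._x = None

    def _out_hw(self, h: int, w: int) -> tuple[int, int]:
        return ((h - 1) * self.s - 2 * self.p + self.k,
                (w - 1) * self.s - 2 * self.p + self.k)

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        if c != self.c_in:
            raise ValueError(f"{self.name}: expected {self.c_in} channels, got {c}")
        if train:
            self._x = x
        h2, w2 = self._out_hw(h, w)
        t = (np.ascontiguousarray(x.transpose(0, 2, 3, 1)).reshape(-1, c) @ self.w.value)
        t = t.reshape(n, h, w, self.c_out, self.k, self.k).transpose(0, 3, 1, 2, 4, 5)
        yp = np.zeros((n, self.c_out, (h - 1) * self.s + self.k,
                       (w - 1) * self.s + self.k), F32)
        for i in range(self.k):
            for j in range(self.k):
                yp[:, :, i:i + self.s * h:self.s, j:j + self.s * w:self.s] += t[..., i, j]
        y = yp[:, :, self.p:self.p + h2, self.p:self.p + w2]
        return y + self.b.value[None, :, None, None]

    def backward(self, gy):
        x = self._x
        n, c, h, w = x.shape
        gyp = np.pad(gy, ((0, 0), (0, 0), (self.p, self.p), (self.p, self.p)))
        win = sliding_window_view(gyp, (self.k, self.k), axis=(2, 3))[:, :, ::self.s, ::self.s]
        win = win[:, :, :h, :w]  # (n, c_out, h, w, k, k)
        wincols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * h * w, self.c_out * self.k * self.k)
        xflat = np.ascontiguousarray(x.transpose(0, 2, 3, 1)).reshape(n * h * w, c)
        self.w.grad += xflat.T @ wincols
        self.b.grad += gy.sum(axis=(0, 2, 3))
        gx = (wincols @ self.w.value.T).reshape(n, h, w, c).transpose(0, 3, 1, 2)
        self._x = None
        return np.ascontiguousarray(gx)

    def params(self):
        return [self.w, self.b]

    def to_ops(self):
        return [{"op": "conv_transpose2d", "k": self.k, "stride": self.s,
                 "pad": self.p, "c_in": self.c_in, "c_out": self.c_out,
                 "weight": self.w.name, "bias": self.b.name}]


class DepthwiseConv2d(Module):
    """Per-channel 3x3 convolution, the depthwise half of a separable conv."""

    def __init__(self, name: str, channels: int, k: int, stride: int, pad: int,
                 rng: np.random.Generator):
        self.name, self.c, self.k, self.s, self.p = name, channels, k, stride, pad
        self.w = Param(f"{name}.w", he_init(rng, (channels, k, k), k * k))
        self.b = Param(f"{name}.b", np.zeros(channels, F32))
        self._xp = None
        self._xshape = None

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        ho = (h + 2 * self.p - self.k) // self.s + 1
        wo = (w + 2 * self.p - self.k) // self.s + 1
        xp = np.pad(x, ((0, 0), (0, 0), (self.p, self.p), (self.p, self.p)))
        if train:
            self._xp, self._xshape = xp, x.shape
        y = np.zeros((n, c, ho, wo), F32)
        for i in range(self.k):
            for j in range(self.k):
                y += self.w.value[None, :, i, j, None, None] * \
                    xp[:, :, i:i + self.s * ho:self.s, j:j + self.s * wo:self.s]
        return y + self.b.value[None, :, None, None]

    def backward(self, gy):
        n, c, h, w = self._xshape
        ho, wo = gy.shape[2:]
        xp = self._xp
        gxp = np.zeros_like(xp)
        for i in range(self.k):
            for j in range(self.k):
                sl = np.s_[:, :, i:i + self.s * ho:self.s, j:j + self.s * wo:self.s]
                self.w.grad[:, i, j] += (gy * xp[sl]).sum(axis=(0, 2, 3))
                gxp[sl] += self.w.value[None, :, i, j, None, None] * gy
        self.b.grad += gy.sum(axis=(0, 2, 3))
        self._xp = None
        return gxp[:, :, self.p:self.p + h, self.p:self.p + w]

    def params(self):
        return [self.w, self.b]

    def to_ops(self):
        return [{"op": "depthwise_conv2d", "k": self.k, "stride": self.s,
                 "pad": self.p, "channels": self.c,
                 "weight": self.w.name, "bias": self.b.name}]


class BatchNorm2d(Module):
    def __init__(self, name: str, channels: int, momentum: float = 0.1,
                 eps: float = 1e-5):
        self.name, self.c, self.momentum, self.eps = name, channels, momentum, eps
        self.gamma = Param(f"{name}.gamma", np.ones(channels, F32))
        self.beta = Param(f"{name}.beta", np.zeros(channels, F32))
        self.running_mean = np.zeros(channels, F32)
        self.running_var = np.ones(channels, F32)
        self._cache = None

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(F32)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(F32)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * invstd[None, :, None, None]
        if train:
            self._cache = (xhat, invstd)
        return (self.gamma.value[None, :, None, None] * xhat
                + self.beta.value[None, :, None, None]).astype(F32)

    def backward(self, gy):
        xhat, invstd = self._cache
        m = gy.shape[0] * gy.shape[2] * gy.shape[3]
        self.gamma.grad += (gy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += gy.sum(axis=(0, 2, 3))
        g = self.gamma.value[None, :, None, None]
        sum_gy = gy.sum(axis=(0, 2, 3))[None, :, None, None]
        sum_gy_xhat = (gy * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        gx = (g * invstd[None, :, None, None] / m) * (m * gy - sum_gy - xhat * sum_gy_xhat)
        self._cache = None
        return gx.astype(F32)

    def params(self):
        return [self.gamma, self.beta]

    def buffers(self):
        return [(f"{self.name}.running_mean", self.running_mean),
                (f"{self.name}.running_var", self.running_var)]

    def to_ops(self):
        return [{"op": "batchnorm2d", "channels": self.c, "eps": self.eps,
                 "gamma": self.gamma.name, "beta": self.beta.name,
                 "mean": f"{self.name}.running_mean",
                 "var": f"{self.name}.running_var"}]


class ReLU(Module):
    def __init__(self):
        self._mask = None

    def forward(self, x, train=False):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, gy):
        gx = gy * self._mask
        self._mask = None
        return gx

    def to_ops(self):
        return [{"op": "relu"}]


class Sigmoid(Module):
    def __init__(self):
        self._y = None

    def forward(self, x, train=False):
        y = 1.0 / (1.0 + np.exp(-x.astype(np.float64)))
        y = y.astype(F32)
        if train:
            self._y = y
        return y

    def backward(self, gy):
        gx = gy * self._y * (1 - self._y)
        self._y = None
        return gx

    def to_ops(self):
        return [{"op": "sigmoid"}]


class MaxPool2d(Module):
    """2x2 max pooling, stride 2; requires even spatial size."""

    def __init__(self):
        self._cache = None

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        y = xr.max(axis=(3, 5))
        if train:
            self._cache = (xr, y, x.shape)
        return y

    def backward(self, gy):
        xr, y, shape = self._cache
        mask = (xr == y[:, :, :, None, :, None])
        # split ties evenly so the gradient mass is conserved
        counts = mask.sum(axis=(3, 5), keepdims=True)
        gx = mask * (gy[:, :, :, None, :, None] / counts)
        self._cache = None
        return gx.reshape(shape).astype(F32)

    def to_ops(self):
        return [{"op": "maxpool2"}]


class GlobalAvgPool(Module):
    def __init__(self):
        self._shape = None

    def forward(self, x, train=False):
        if train:
            self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, gy):
        n, c, h, w = self._shape
        gx = np.broadcast_to(gy[:, :, None, None] / (h * w), self._shape)
        self._shape = None
        return np.ascontiguousarray(gx, dtype=F32)

    def to_ops(self):
        return [{"op": "global_avg_pool"}]


class Flatten(Module):
    def __init__(self):
        self._shape = None

    def forward(self, x, train=False):
        if train:
            self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gy):
        gx = gy.reshape(self._shape)
        self._shape = None
        return gx

    def to_ops(self):
        return [{"op": "flatten"}]


class Linear(Module):
    def __init__(self, name: str, n_in: int, n_out: int, rng: np.random.Generator):
        self.name, self.n_in, self.n_out = name, n_in, n_out
        self.w = Param(f"{name}.w", he_init(rng, (n_in, n_out), n_in))
        self.b = Param(f"{name}.b", np.zeros(n_out, F32))
        self._x = None

    def forward(self, x, train=False):
        if x.ndim != 2 or x.shape[1] != self.n_in:
            raise ValueError(f"{self.name}: expected (n, {self.n_in}), got {x.shape}")
        if train:
            self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, gy):
        self.w.grad += self._x.T @ gy
        self.b.grad += gy.sum(axis=0)
        gx = gy @ self.w.value.T
        self._x = None
        return gx

    def params(self):
        return [self.w, self.b]

    def to_ops(self):
        return [{"op": "linear", "n_in": self.n_in, "n_out": self.n_out,
                 "weight": self.w.name, "bias": self.b.name}]


class Sequential(Module):
    def __init__(self, *modules: Module):
        self.modules = list(modules)

    def forward(self, x, train=False):
        for m in self.modules:
            x = m.forward(x, train=train)
        return x

    def backward(self, gy):
        for m in reversed(self.modules):
            gy = m.backward(gy)
        return gy

    def params(self):
        return [p for m in self.modules for p in m.params()]

    def buffers(self):
        return [b for m in self.modules for b in m.buffers()]

    def to_ops(self):
        return [op for m in self.modules for op in m.to_ops()]


class Residual(Module):
    """y = act(main(x) + shortcut(x)); shortcut=None is the identity skip.

    ``post_relu=False`` gives the MobileNet-style linear residual add.
    """

    def __init__(self, main: Module, shortcut: Module | None = None,
                 post_relu: bool = True):
        self.main = main
        self.shortcut = shortcut
        self.post_relu = post_relu
        self._mask = None

    def forward(self, x, train=False):
        y = self.main.forward(x, train=train)
        s = self.shortcut.forward(x, train=train) if self.shortcut is not None else x
        out = y + s
        if self.post_relu:
            if train:
                self._mask = out > 0
            out = np.maximum(out, 0)
        return out

    def backward(self, gy):
        if self.post_relu:
            gy = gy * self._mask
            self._mask = None
        gx = self.main.backward(gy)
        if self.shortcut is not None:
            gx = gx + self.shortcut.backward(gy)
        else:
            gx = gx + gy
        return gx

    def params(self):
        return self.main.params() + (self.shortcut.params() if self.shortcut else [])

    def buffers(self):
        return self.main.buffers() + (self.shortcut.buffers() if self.shortcut else [])

    def to_ops(self):
        return [{"op": "residual", "post_relu": self.post_relu,
                 "main": self.main.to_ops(),
                 "shortcut": self.shortcut.to_ops() if self.shortcut else None}]


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error over every element; returns (loss, dloss/dpred)."""
    diff = pred.astype(np.float64) - target.astype(np.float64)
    loss = float(np.mean(diff * diff))
    grad = (2.0 / diff.size) * diff
    return loss, grad.astype(F32)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy_loss(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy for integer class targets; returns (loss, dloss/dlogits)."""
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    eps = 1e-12
    loss = float(-np.mean(np.log(p[np.arange(n), targets] + eps)))
    grad = p
    grad[np.arange(n), targets] -= 1.0
    return loss, (grad / n).astype(F32)


# ---------------------------------------------------------------------------
# optimization
# ---------------------------------------------------------------------------

class Adam:
    def __init__(self, params: Iterable[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0

    def step(self):
        self.t += 1
        bc1 = 1 - self.b1 ** self.t
        bc2 = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * (p.grad * p.grad)
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


class ReduceLROnPlateau:
    """Multiply lr by ``factor`` after ``patience`` epochs without improvement."""

    def __init__(self, optimizer: Adam, patience: int = 2, factor: float = 0.1,
                 min_lr: float = 1e-7):
        self.opt = optimizer
        self.patience = patience
        self.factor = factor
        self.min_lr = min_lr
        self.best = np.inf
        self.bad_epochs = 0

    def step(self, metric: float) -> None:
        if metric < self.best - 1e-12:
            self.best = metric
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
            if self.bad_epochs > self.patience:
                self.opt.lr = max(self.opt.lr * self.factor, self.min_lr)
                self.bad_epochs = 0


# ---------------------------------------------------------------------------
# (de)serialization
# ---------------------------------------------------------------------------

def state_dict(net: Module) -> dict[str, np.ndarray]:
    state = {p.name: p.value for p in net.params()}
    for name, buf in net.buffers():
        state[name] = buf
    return state


def load_state_dict(net: Module, state: dict[str, np.ndarray]) -> None:
    for p in net.params():
        if p.name not in state:
            raise KeyError(f"missing parameter {p.name!r} in checkpoint")
        if state[p.name].shape != p.value.shape:
            raise ValueError(f"shape mismatch for {p.name!r}")
        p.value[...] = state[p.name]
    # rebind buffers in place so running stats survive a round-trip
    stack: list[Module] = [net]
    while stack:
        m = stack.pop()
        if isinstance(m, BatchNorm2d):
            m.running_mean[...] = state[f"{m.name}.running_mean"]
            m.running_var[...] = state[f"{m.name}.running_var"]
        elif isinstance(m, Sequential):
            stack.extend(m.modules)
        elif isinstance(m, Residual):
            stack.append(m.main)
            if m.shortcut is not None:
                stack.append(m.shortcut)


def iterate_minibatches(n: int, batch_size: int,
                        rng: np.random.Generator) -> Iterable[np.ndarray]:
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]
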