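"""Minimal numpy neural-network engine: reverse-mode autograd and the layers
needed by the two-stream residual network (conv, batch-norm, pooling, linear),
plus the Adam optimizer and a softmax cross-entropy loss.

Conventions
-----------
* Activations are NCHW ``float64`` arrays wrapped in :class:`Tensor`.
* ``Tensor.backward()`` runs reverse-mode differentiation over the recorded
  graph; every node in the graph receives a ``.grad`` array (useful for
  activation-level analyses such as gradient-weighted class activation maps).
* Layers are :class:`Module` objects holding :class:`Parameter` leaves; a
  parameter can be frozen (``trainable = False``), which excludes it from the
  optimizer and from gradient accumulation cost.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "Module",
    "Conv2d",
    "BatchNorm2d",
    "Linear",
    "Adam",
    "add",
    "scale",
    "relu",
    "matmul",
    "conv2d",
    "maxpool2d",
    "global_avg_pool",
    "concat",
    "cross_entropy",
    "softmax",
]


# ---------------------------------------------------------------------------
# autograd core
# ---------------------------------------------------------------------------

class Tensor:
    """A numpy array plus the bookkeeping for reverse-mode differentiation."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def zero_grad(self):
        self.grad = None

    def backward(self, seed=None):
        """Backpropagate from this node. ``seed`` defaults to ones."""
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(node: Tensor):
            stack = [(node, False)]
            while stack:
                n, processed = stack.pop()
                if processed:
                    topo.append(n)
                    continue
                if id(n) in seen:
                    continue
                seen.add(id(n))
                stack.append((n, True))
                for p in n._parents:
                    stack.append((p, False))

        visit(self)
        self.grad = (
            np.ones_like(self.data) if seed is None else np.asarray(seed, dtype=np.float64)
        )
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


class Parameter(Tensor):
    """A trainable leaf tensor. ``trainable=False`` freezes it."""

    __slots__ = ("trainable",)

    def __init__(self, data, trainable=True):
        super().__init__(data, requires_grad=True)
        self.trainable = trainable


def _accumulate(t: Tensor, g: np.ndarray):
    if t.grad is None:
        t.grad = g.copy()
    else:
        t.grad += g


def _as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------------
# primitive ops
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        _accumulate(a, _unbroadcast(g, a.data.shape))
        _accumulate(b, _unbroadcast(g, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward=backward)


def scale(a: Tensor, s: float) -> Tensor:
    a = _as_tensor(a)
    s = float(s)

    def backward(g):
        _accumulate(a, g * s)

    return Tensor(a.data * s, parents=(a,), backward=backward)


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def relu(a: Tensor) -> Tensor:
    a = _as_tensor(a)
    mask = a.data > 0

    def backward(g):
        _accumulate(a, g * mask)

    return Tensor(a.data * mask, parents=(a,), backward=backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)

    def backward(g):
        _accumulate(a, g @ b.data.T)
        _accumulate(b, a.data.T @ g)

    return Tensor(a.data @ b.data, parents=(a, b), backward=backward)


def concat(a: Tensor, b: Tensor, axis: int = 1) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    na = a.data.shape[axis]

    def backward(g):
        ga, gb = np.split(g, [na], axis=axis)
        _accumulate(a, ga)
        _accumulate(b, gb)

    return Tensor(np.concatenate([a.data, b.data], axis=axis), parents=(a, b), backward=backward)


# ---------------------------------------------------------------------------
# convolution via im2col / col2im
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = x.shape
    hp = (h + 2 * pad - kh) // stride + 1
    wp = (w + 2 * pad - kw) // stride + 1
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    windows = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    windows = windows[:, :, ::stride, ::stride]  # (n, c, hp, wp, kh, kw)
    cols = windows.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * kh * kw, hp * wp)
    return np.ascontiguousarray(cols), hp, wp


def _col2im(dcols: np.ndarray, x_shape, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = x_shape
    hp = (h + 2 * pad - kh) // stride + 1
    wp = (w + 2 * pad - kw) // stride + 1
    dx = np.zeros((n, c, h + 2 * pad, w + 2 * pad))
    d6 = dcols.reshape(n, c, kh, kw, hp, wp)
    for i in range(kh):
        for j in range(kw):
            dx[:, :, i : i + stride * hp : stride, j : j + stride * wp : stride] += d6[:, :, i, j]
    if pad:
        dx = dx[:, :, pad : pad + h, pad : pad + w]
    return dx


def conv2d(x: Tensor, weight: Tensor, stride: int = 1, pad: int = 0) -> Tensor:
    """2-D cross-correlation, NCHW, no bias (batch norm follows each conv)."""
    x, weight = _as_tensor(x), _as_tensor(weight)
    f, c, kh, kw = weight.data.shape
    cols, hp, wp = _im2col(x.data, kh, kw, stride, pad)
    wmat = weight.data.reshape(f, c * kh * kw)
    out = np.einsum("fk,nkp->nfp", wmat, cols).reshape(x.data.shape[0], f, hp, wp)

    def backward(g):
        gmat = g.reshape(g.shape[0], f, hp * wp)
        if weight.requires_grad:
            dw = np.einsum("nfp,nkp->fk", gmat, cols).reshape(weight.data.shape)
            _accumulate(weight, dw)
        dcols = np.einsum("fk,nfp->nkp", wmat, gmat)
        _accumulate(x, _col2im(dcols, x.data.shape, kh, kw, stride, pad))

    return Tensor(out, parents=(x, weight), backward=backward)


def maxpool2d(x: Tensor, kernel: int = 3, stride: int = 2, pad: int = 1) -> Tensor:
    x = _as_tensor(x)
    n, c, h, w = x.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)), constant_values=-np.inf)
    windows = np.lib.stride_tricks.sliding_window_view(xp, (kernel, kernel), axis=(2, 3))
    windows = windows[:, :, ::stride, ::stride]  # (n, c, hp, wp, k, k)
    hp, wp = windows.shape[2], windows.shape[3]
    flat = windows.reshape(n, c, hp, wp, kernel * kernel)
    arg = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

    def backward(g):
        onehot = np.zeros_like(flat)
        np.put_along_axis(onehot, arg[..., None], g[..., None], axis=-1)
        dcols = onehot.reshape(n, c, hp, wp, kernel, kernel).transpose(0, 1, 4, 5, 2, 3)
        dcols = dcols.reshape(n, c * kernel * kernel, hp * wp)
        dxp = _col2im(dcols, (n, c, h, w), kernel, kernel, stride, pad)
        _accumulate(x, dxp)

    return Tensor(out, parents=(x,), backward=backward)


def global_avg_pool(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    n, c, h, w = x.data.shape

    def backward(g):
        _accumulate(x, np.broadcast_to(g[:, :, None, None] / (h * w), x.data.shape))

    return Tensor(x.data.mean(axis=(2, 3)), parents=(x,), backward=backward)


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy; ``labels`` are integer class indices."""
    logits = _as_tensor(logits)
    labels = np.asarray(labels, dtype=np.int64)
    p = softmax(logits.data)
    n = logits.data.shape[0]
    nll = -np.log(np.clip(p[np.arange(n), labels], 1e-300, None))

    def backward(g):
        d = p.copy()
        d[np.arange(n), labels] -= 1.0
        _accumulate(logits, (g * d) / n)

    return Tensor(nll.mean(), parents=(logits,), backward=backward)


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------

class Module:
    """Base class: tracks sub-modules and parameters, train/eval mode."""

    def __init__(self):
        self.training = True

    def modules(self):
        out = [self]

        def scan(value):
            if isinstance(value, Module):
                out.extend(value.modules())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    scan(item)

        for v in self.__dict__.values():
            scan(v)
        return out

    def parameters(self):
        params = []
        for m in self.modules():
            for v in m.__dict__.values():
                if isinstance(v, Parameter):
                    params.append(v)
        return params

    def train(self):
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int, pad: int, rng: np.random.Generator):
        super().__init__()
        self.stride, self.pad = stride, pad
        fan_in = in_ch * kernel * kernel
        std = np.sqrt(2.0 / fan_in)  # He initialization for ReLU nets
        self.weight = Parameter(rng.normal(0.0, std, size=(out_ch, in_ch, kernel, kernel)))

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, stride=self.stride, pad=self.pad)


class BatchNorm2d(Module):
    """Batch normalization over N, H, W with running statistics for eval."""

    def __init__(self, num_ch: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(num_ch))
        self.beta = Parameter(np.zeros(num_ch))
        self.running_mean = np.zeros(num_ch)
        self.running_var = np.ones(num_ch)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        gamma, beta = self.gamma, self.beta
        if self.training:
            mean = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mean[None, :, None, None]) * invstd[None, :, None, None]
        out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]
        m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
        training = self.training

        def backward(g):
            dgamma = (g * xhat).sum(axis=(0, 2, 3))
            dbeta = g.sum(axis=(0, 2, 3))
            if gamma.requires_grad:
                _accumulate(gamma, dgamma)
                _accumulate(beta, dbeta)
            gi = gamma.data[None, :, None, None] * invstd[None, :, None, None]
            if training:
                dx = gi / m * (
                    m * g
                    - dbeta[None, :, None, None]
                    - xhat * dgamma[None, :, None, None]
                )
            else:
                dx = gi * g
            _accumulate(x, dx)

        return Tensor(out, parents=(x, gamma, beta), backward=backward)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        bound = 1.0 / np.sqrt(in_dim)
        self.weight = Parameter(rng.uniform(-bound, bound, size=(in_dim, out_dim)))
        self.bias = Parameter(rng.uniform(-bound, bound, size=(out_dim,))) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = matmul(x, self.weight)
        if self.bias is not None:
            out = add(out, self.bias)
        return out


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params, lr: float, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = [p for p in params if p.trainable]
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()


class SGD:
    """SGD with optional momentum (0.9 reproduces the usual comparison setup)."""

    def __init__(self, params, lr: float, momentum: float = 0.9):
        self.params = [p for p in params if p.trainable]
        self.lr = lr
        self.momentum = momentum
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.v[i] = self.momentum * self.v[i] + p.grad
            p.data -= self.lr * self.v[i]

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()


class RMSprop:
    def __init__(self, params, lr: float, alpha: float = 0.99, eps: float = 1e-8):
        self.params = [p for p in params if p.trainable]
        self.lr, self.alpha, self.eps = lr, alpha, eps
        self.s = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.s[i] = self.alpha * self.s[i] + (1 - self.alpha) * p.grad ** 2
            p.data -= self.lr * p.grad / (np.sqrt(self.s[i]) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()


class NAdam(Adam):
    """Adam with Nesterov momentum applied to the first moment."""

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = (self.b1 * self.m[i] + (1 - self.b1) * g) / (1 - self.b1 ** (self.t + 1))
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


OPTIMIZERS = {"adam": Adam, "sgd": SGD, "rmsprop": RMSprop, "nadam": NAdam}
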