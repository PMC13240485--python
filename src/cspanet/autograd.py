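"""Minimal reverse-mode automatic differentiation over NumPy arrays.

This module provides exactly the primitives needed by the classifier:
2D convolution (via im2col + GEMM), a 1D convolution along a channel
vector, batch normalization, dense layers, elementwise nonlinearities,
axis reductions, concatenation, and a fused softmax cross-entropy loss.
Gradients are accumulated by a topological backward sweep over the tape.

Everything is plain NumPy; float32 is used for model weights by default,
but the ops are dtype-agnostic so tests can gradient-check in float64.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor", "Parameter", "Module", "Adam",
    "add", "mul", "reshape", "concat", "relu", "sigmoid",
    "reduce_mean", "reduce_max", "conv2d", "conv1d_channels",
    "batch_norm", "linear", "softmax_cross_entropy", "softmax",
]


# ---------------------------------------------------------------------------
# Tensor and tape
# ---------------------------------------------------------------------------

class Tensor:
    """A NumPy array plus an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents: tuple = ()
        self._backward = None

    # -- convenience -------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def __add__(self, other):
        return add(self, _as_tensor(other))

    def __radd__(self, other):
        return add(_as_tensor(other), self)

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    def __rmul__(self, other):
        return mul(_as_tensor(other), self)

    def __sub__(self, other):
        return add(self, mul(_as_tensor(other), _as_tensor(-1.0)))

    def __neg__(self):
        return mul(self, _as_tensor(-1.0))

    # -- backward sweep ----------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; deep nets overflow recursion limits
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        _accum(self, np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _accum(t: Tensor, g: np.ndarray) -> None:
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = g.copy() if g.base is not None or g.flags.writeable is False else g
    else:
        t.grad = t.grad + g


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(p for p in parents if p.requires_grad)
        out._backward = backward
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum a gradient down to the shape it was broadcast from."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


# ---------------------------------------------------------------------------
# Elementwise and structural ops
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)

    def backward(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(g, b.data.shape))

    return _make(a.data + b.data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)

    def backward(g):
        _accum(a, _unbroadcast(g * b.data, a.data.shape))
        _accum(b, _unbroadcast(g * a.data, b.data.shape))

    return _make(a.data * b.data, (a, b), backward)


def reshape(x: Tensor, shape) -> Tensor:
    x = _as_tensor(x)
    old = x.data.shape

    def backward(g):
        _accum(x, g.reshape(old))

    return _make(x.data.reshape(shape), (x,), backward)


def concat(tensors, axis: int) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            _accum(t, piece)

    return _make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward)


def relu(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    mask = x.data > 0

    def backward(g):
        _accum(x, g * mask)

    return _make(np.where(mask, x.data, 0), (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    s = 1.0 / (1.0 + np.exp(-x.data))

    def backward(g):
        _accum(x, g * s * (1.0 - s))

    return _make(s, (x,), backward)


def reduce_mean(x: Tensor, axis, keepdims: bool = False) -> Tensor:
    x = _as_tensor(x)
    axis = (axis,) if isinstance(axis, int) else tuple(axis)
    n = int(np.prod([x.data.shape[a] for a in axis]))
    out = x.data.mean(axis=axis, keepdims=keepdims)

    def backward(g):
        if not keepdims:
            g = np.expand_dims(g, axis)
        _accum(x, np.broadcast_to(g / n, x.data.shape))

    return _make(out, (x,), backward)


def reduce_max(x: Tensor, axis, keepdims: bool = False) -> Tensor:
    x = _as_tensor(x)
    axis = (axis,) if isinstance(axis, int) else tuple(axis)
    mx = x.data.max(axis=axis, keepdims=True)
    out = mx if keepdims else mx.reshape(
        [s for i, s in enumerate(x.data.shape) if i not in axis])

    def backward(g):
        if not keepdims:
            g = np.expand_dims(g, axis)
        mask = x.data == mx
        count = mask.sum(axis=axis, keepdims=True)
        _accum(x, mask * (g / count))

    return _make(out, (x,), backward)


# ---------------------------------------------------------------------------
# Convolutions
# ---------------------------------------------------------------------------

def _pair(v):
    return (v, v) if isinstance(v, int) else tuple(v)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride=1, padding=0) -> Tensor:
    """2D cross-correlation, NCHW input, OIHW kernel, zero padding."""
    x, w = _as_tensor(x), _as_tensor(w)
    sh, sw = _pair(stride)
    ph, pw = _pair(padding)
    N, C, H, W = x.data.shape
    O, I, kh, kw = w.data.shape
    if I != C:
        raise ValueError(f"conv2d: kernel expects {I} input channels, got {C}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw))) if (ph or pw) else x.data
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::sh, ::sw]
    Ho, Wo = win.shape[2], win.shape[3]
    col = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(N * Ho * Wo, C * kh * kw)
    wmat = w.data.reshape(O, -1)
    out = col @ wmat.T
    if b is not None:
        out = out + b.data
    out4 = np.ascontiguousarray(out.reshape(N, Ho, Wo, O).transpose(0, 3, 1, 2))

    def backward(g):
        g2 = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(N * Ho * Wo, O)
        if w.requires_grad:
            _accum(w, (g2.T @ col).reshape(w.data.shape))
        if b is not None and b.requires_grad:
            _accum(b, g2.sum(axis=0))
        if x.requires_grad:
            dcol = g2 @ wmat
            dwin = dcol.reshape(N, Ho, Wo, C, kh, kw)
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i:i + (Ho - 1) * sh + 1:sh, j:j + (Wo - 1) * sw + 1:sw] += \
                        dwin[:, :, :, :, i, j].transpose(0, 3, 1, 2)
            gx = gxp[:, :, ph:ph + H, pw:pw + W] if (ph or pw) else gxp
            _accum(x, gx)

    parents = (x, w) if b is None else (x, w, b)
    return _make(out4, parents, backward)


def conv1d_channels(v: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """1D cross-correlation along the channel axis of a (N, C) descriptor.

    Zero padding of (k-1)/2 on both sides keeps the output length at C.
    """
    v, w = _as_tensor(v), _as_tensor(w)
    (k,) = w.data.shape
    if k % 2 != 1:
        raise ValueError("conv1d_channels: kernel size must be odd")
    p = (k - 1) // 2
    N, C = v.data.shape
    vp = np.pad(v.data, ((0, 0), (p, p))) if p else v.data
    win = sliding_window_view(vp, k, axis=1)  # (N, C, k)
    out = win @ w.data
    if b is not None:
        out = out + b.data

    def backward(g):
        if w.requires_grad:
            _accum(w, np.einsum("nck,nc->k", win, g))
        if b is not None and b.requires_grad:
            _accum(b, np.asarray(g.sum()).reshape(b.data.shape))
        if v.requires_grad:
            gvp = np.zeros_like(vp)
            for j in range(k):
                gvp[:, j:j + C] += g * w.data[j]
            _accum(v, gvp[:, p:p + C] if p else gvp)

    parents = (v, w) if b is None else (v, w, b)
    return _make(out, parents, backward)


# ---------------------------------------------------------------------------
# Batch normalization, dense layer, loss
# ---------------------------------------------------------------------------

def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor,
               running_mean: np.ndarray, running_var: np.ndarray,
               training: bool, momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Batch normalization over all axes except the channel axis (axis 1).

    ``running_mean``/``running_var`` are plain arrays updated in place
    during training and used verbatim at evaluation time.
    """
    x = _as_tensor(x)
    axes = (0,) if x.data.ndim == 2 else (0, 2, 3)
    bshape = [1] * x.data.ndim
    bshape[1] = x.data.shape[1]
    if training:
        mu = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        running_mean *= (1 - momentum)
        running_mean += momentum * mu
        running_var *= (1 - momentum)
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu.reshape(bshape)) * inv.reshape(bshape)
    out = gamma.data.reshape(bshape) * xhat + beta.data.reshape(bshape)
    m = x.data.size // x.data.shape[1]

    def backward(g):
        if gamma.requires_grad:
            _accum(gamma, (g * xhat).sum(axis=axes))
        if beta.requires_grad:
            _accum(beta, g.sum(axis=axes))
        if x.requires_grad:
            dxhat = g * gamma.data.reshape(bshape)
            if training:
                gx = inv.reshape(bshape) * (
                    dxhat
                    - dxhat.mean(axis=axes, keepdims=True)
                    - xhat * (dxhat * xhat).sum(axis=axes, keepdims=True) / m
                )
            else:
                gx = dxhat * inv.reshape(bshape)
            _accum(x, gx)

    return _make(out, (x, gamma, beta), backward)


def linear(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Dense layer: x (N, in) @ w (in, out) + b."""
    x, w = _as_tensor(x), _as_tensor(w)
    out = x.data @ w.data
    if b is not None:
        out = out + b.data

    def backward(g):
        if w.requires_grad:
            _accum(w, x.data.T @ g)
        if b is not None and b.requires_grad:
            _accum(b, g.sum(axis=0))
        if x.requires_grad:
            _accum(x, g @ w.data.T)

    parents = (x, w) if b is None else (x, w, b)
    return _make(out, parents, backward)


def softmax(logits: np.ndarray) -> np.ndarray:
    """Numerically stable softmax over the last axis (plain array helper)."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy between softmax(logits) and integer labels."""
    logits = _as_tensor(logits)
    labels = np.asarray(labels)
    N = logits.data.shape[0]
    probs = softmax(logits.data)
    idx = np.arange(N)
    eps = np.finfo(probs.dtype).tiny
    loss = -np.log(np.maximum(probs[idx, labels], eps)).mean()

    def backward(g):
        if logits.requires_grad:
            d = probs.copy()
            d[idx, labels] -= 1.0
            _accum(logits, (g / N) * d)

    return _make(np.asarray(loss, dtype=logits.data.dtype), (logits,), backward)


# ---------------------------------------------------------------------------
# Modules and optimizer
# ---------------------------------------------------------------------------

class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


class Module:
    """Parameter container with recursive discovery of children.

    Children are found by scanning instance attributes for Parameter,
    Module, and lists/tuples thereof, in attribute insertion order, which
    makes checkpoint key naming deterministic.
    """

    training: bool = True

    def named_parameters(self, prefix: str = ""):
        for name, child, kind in self._children():
            full = f"{prefix}{name}"
            if kind == "param":
                yield full, child
            else:
                yield from child.named_parameters(prefix=full + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for name, buf in getattr(self, "_buffers", {}).items():
            yield f"{prefix}{name}", buf
        for name, child, kind in self._children():
            if kind == "module":
                yield from child.named_buffers(prefix=f"{prefix}{name}.")

    def _children(self):
        for name, value in self.__dict__.items():
            if isinstance(value, Parameter):
                yield name, value, "param"
            elif isinstance(value, Module):
                yield name, value, "module"
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item, "module"
                    elif isinstance(item, Parameter):
                        yield f"{name}.{i}", item, "param"

    def modules(self):
        yield self
        for _, child, kind in self._children():
            if kind == "module":
                yield from child.modules()

    def set_training(self, flag: bool):
        for m in self.modules():
            m.training = flag
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Adam:
    """Adam optimizer with bias correction (library-standard defaults)."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * (g * g)
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
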