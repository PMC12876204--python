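"""Minimal vectorized reverse-mode automatic differentiation on NumPy.

The network code in :mod:`sksformer.model` needs gradients through a graph
with branching paths (two attention branches re-using the encoder output,
a gate that multiplies both), so manual backprop would be error-prone.
This module provides a small tensor type with exactly the operations the
model needs — broadcasting arithmetic, batched matmul, reductions, softmax,
grouped 1-D convolution — plus a module system, Adam, and cross-entropy.

All tensors are float32. Gradients are accumulated into ``Tensor.grad`` as
plain ndarrays. Operations only record the graph when a participating input
requires gradients, so inference builds no graph.
"""

from __future__ import annotations

import math

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph recording (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast from ``shape``."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An ndarray with an optional gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward_fn")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward_fn = None

    # -- housekeeping -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def _accumulate(self, g: np.ndarray) -> None:
        g = _unbroadcast(g, self.data.shape)
        self.grad = g if self.grad is None else self.grad + g

    def backward(self, grad: np.ndarray | None = None) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data) if grad is None else np.asarray(grad, dtype=DTYPE)
        for node in reversed(topo):
            if node._backward_fn is not None:
                node._backward_fn()
        # break the closure<->tensor reference cycles so the graph's large
        # intermediate arrays are freed by refcounting, not delayed gc;
        # leaves (no backward fn, e.g. Parameters) keep their grads
        for node in topo:
            if node._backward_fn is not None:
                node._backward_fn = None
                node._parents = ()
                if node is not self:
                    node.grad = None

    # -- graph construction helper ------------------------------------
    @staticmethod
    def _make(data, parents, backward_fn):
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(p for p in parents if p.requires_grad)
            out._backward_fn = backward_fn
        return out

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_holder = {}

        def bw():
            g = out_holder["out"].grad
            if self.requires_grad:
                self._accumulate(g)
            if other.requires_grad:
                other._accumulate(g)

        out = Tensor._make(self.data + other.data, (self, other), bw)
        out_holder["out"] = out
        return out

    __radd__ = __add__

    def __neg__(self):
        out_holder = {}

        def bw():
            if self.requires_grad:
                self._accumulate(-out_holder["out"].grad)

        out = Tensor._make(-self.data, (self,), bw)
        out_holder["out"] = out
        return out

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_holder = {}

        def bw():
            g = out_holder["out"].grad
            if self.requires_grad:
                self._accumulate(g * other.data)
            if other.requires_grad:
                other._accumulate(g * self.data)

        out = Tensor._make(self.data * other.data, (self, other), bw)
        out_holder["out"] = out
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return Tensor(other) * self ** -1.0

    def __pow__(self, exponent: float):
        out_holder = {}

        def bw():
            if self.requires_grad:
                self._accumulate(
                    out_holder["out"].grad * exponent * self.data ** (exponent - 1.0)
                )

        out = Tensor._make(self.data ** exponent, (self,), bw)
        out_holder["out"] = out
        return out

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_holder = {}

        def bw():
            g = out_holder["out"].grad
            if self.requires_grad:
                self._accumulate(g @ np.swapaxes(other.data, -1, -2))
            if other.requires_grad:
                other._accumulate(np.swapaxes(self.data, -1, -2) @ g)

        out = Tensor._make(self.data @ other.data, (self, other), bw)
        out_holder["out"] = out
        return out

    # -- shape ops ------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        out_holder = {}

        def bw():
            if self.requires_grad:
                self._accumulate(out_holder["out"].grad.reshape(orig))

        out = Tensor._make(self.data.reshape(shape), (self,), bw)
        out_holder["out"] = out
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out_holder = {}

        def bw():
            if self.requires_grad:
                self._accumulate(out_holder["out"].grad.transpose(inv))

        out = Tensor._make(self.data.transpose(axes), (self,), bw)
        out_holder["out"] = out
        return out

    def contiguous(self) -> "Tensor":
        """Copy to C order; keeps reduction order independent of layout."""
        out_holder = {}

        def bw():
            if self.requires_grad:
                self._accumulate(out_holder["out"].grad)

        out = Tensor._make(np.ascontiguousarray(self.data), (self,), bw)
        out_holder["out"] = out
        return out

    def swapaxes(self, a: int, b: int):
        axes = list(range(self.ndim))
        axes[a], axes[b] = axes[b], axes[a]
        return self.transpose(*axes)

    # -- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        orig_shape = self.data.shape
        out_holder = {}

        def bw():
            if not self.requires_grad:
                return
            g = out_holder["out"].grad
            if axis is None:
                self._accumulate(np.broadcast_to(g, orig_shape).copy())
                return
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            if not keepdims:
                for ax in sorted(a % len(orig_shape) for a in axes):
                    g = np.expand_dims(g, ax)
            self._accumulate(np.broadcast_to(g, orig_shape).copy())

        out = Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)
        out_holder["out"] = out
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- elementwise nonlinearities --------------------------------------
    def exp(self):
        out_holder = {}

        def bw():
            if self.requires_grad:
                self._accumulate(out_holder["out"].grad * out_holder["out"].data)

        out = Tensor._make(np.exp(self.data), (self,), bw)
        out_holder["out"] = out
        return out

    def log(self):
        out_holder = {}

        def bw():
            if self.requires_grad:
                self._accumulate(out_holder["out"].grad / self.data)

        out = Tensor._make(np.log(self.data), (self,), bw)
        out_holder["out"] = out
        return out

    def relu(self):
        out_holder = {}
        mask = self.data > 0

        def bw():
            if self.requires_grad:
                self._accumulate(out_holder["out"].grad * mask)

        out = Tensor._make(np.where(mask, self.data, 0.0), (self,), bw)
        out_holder["out"] = out
        return out

    def sigmoid(self):
        out_holder = {}
        s = 1.0 / (1.0 + np.exp(-self.data))

        def bw():
            if self.requires_grad:
                self._accumulate(out_holder["out"].grad * s * (1.0 - s))

        out = Tensor._make(s, (self,), bw)
        out_holder["out"] = out
        return out


# ---------------------------------------------------------------------------
# functional ops
# ---------------------------------------------------------------------------

def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Fused softmax: y = exp(x - max) / Σ, backward dx = y·(g − Σ g·y)."""
    z = x.data - x.data.max(axis=axis, keepdims=True)
    np.exp(z, out=z)
    z /= z.sum(axis=axis, keepdims=True)
    out_holder = {}

    def bw():
        if x.requires_grad:
            g = out_holder["out"].grad
            y = out_holder["out"].data
            gy = g * y
            x._accumulate(gy - y * gy.sum(axis=axis, keepdims=True))

    out = Tensor._make(z, (x,), bw)
    out_holder["out"] = out
    return out


def scaled_dot_attention(q: Tensor, k: Tensor, v: Tensor, scale: float):
    """Fused softmax(q·kᵀ·scale)·v with a single-pass analytic backward.

    Shapes: q, k, v are (..., T, d); returns ((..., T, d), attention map).
    Kept as one primitive because the (..., T, T) intermediates dominate
    the model's runtime; fusing avoids materializing them repeatedly.
    """
    s = (q.data * scale) @ np.swapaxes(k.data, -1, -2)
    s -= s.max(axis=-1, keepdims=True)
    np.exp(s, out=s)
    s /= s.sum(axis=-1, keepdims=True)
    attn = s                                   # row-stochastic map
    out_data = attn @ v.data
    out_holder = {}

    def bw():
        g = out_holder["out"].grad
        if v.requires_grad:
            v._accumulate(np.swapaxes(attn, -1, -2) @ g)
        if q.requires_grad or k.requires_grad:
            da = g @ np.swapaxes(v.data, -1, -2)
            da *= attn
            da -= attn * da.sum(axis=-1, keepdims=True)   # dS (softmax jvp)
            if q.requires_grad:
                q._accumulate((da @ k.data) * scale)
            if k.requires_grad:
                k._accumulate(np.swapaxes(da, -1, -2) @ (q.data * scale))

    out = Tensor._make(out_data, (q, k, v), bw)
    out_holder["out"] = out
    return out, attn


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    z = x - shift
    return z - z.exp().sum(axis=axis, keepdims=True).log()


def cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean categorical cross-entropy of integer ``targets`` under ``logits``."""
    n, k = logits.shape
    onehot = np.zeros((n, k), dtype=DTYPE)
    onehot[np.arange(n), np.asarray(targets, dtype=np.intp)] = 1.0
    return (log_softmax(logits, axis=1) * Tensor(onehot)).sum() * (-1.0 / n)


def conv1d(x: Tensor, weight: Tensor, bias: Tensor | None = None, groups: int = 1) -> Tensor:
    """Grouped 1-D convolution over the last axis with same-padding.

    ``x``: (B, C_in, T); ``weight``: (C_out, C_in/groups, k) with odd k.
    """
    b_n, c_in, t = x.shape
    c_out, cpg, k = weight.shape
    if k % 2 == 0:
        raise ValueError("conv1d requires an odd kernel size for same-padding")
    if c_in % groups or c_out % groups or cpg != c_in // groups:
        raise ValueError("inconsistent channel/group counts")
    pad = k // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad)))
    win = sliding_window_view(xp, k, axis=2)  # (B, C_in, T, k) view
    wing = win.reshape(b_n, groups, cpg, t, k)
    wg = weight.data.reshape(groups, c_out // groups, cpg, k)
    out_data = np.einsum("bgctk,gock->bgot", wing, wg, optimize=True).reshape(b_n, c_out, t)
    if bias is not None:
        out_data = out_data + bias.data[None, :, None]
    parents = (x, weight) if bias is None else (x, weight, bias)
    out_holder = {}

    def bw():
        g = out_holder["out"].grad
        gg = g.reshape(b_n, groups, c_out // groups, t)
        if weight.requires_grad:
            dw = np.einsum("bgot,bgctk->gock", gg, wing, optimize=True)
            weight._accumulate(dw.reshape(c_out, cpg, k))
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2)))
        if x.requires_grad:
            dwin = np.einsum("bgot,gock->bgctk", gg, wg, optimize=True)
            dwin = dwin.reshape(b_n, c_in, t, k)
            dxp = np.zeros_like(xp)
            for j in range(k):
                dxp[:, :, j : j + t] += dwin[..., j]
            x._accumulate(dxp[:, :, pad : pad + t])

    out = Tensor._make(out_data, parents, bw)
    out_holder["out"] = out
    return out


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------

class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Container with recursive parameter discovery and train/eval mode."""

    # names of plain-ndarray attributes to include in state (e.g. BN stats)
    _state_attrs: tuple[str, ...] = ()

    def __init__(self):
        self.training = True

    def _children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                yield prefix + name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Parameter):
                        yield f"{prefix}{name}.{i}", item
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_modules(self, prefix: str = ""):
        yield prefix.rstrip("."), self
        for name, child in self._children():
            yield from child.named_modules(prefix + name + ".")

    def train(self, mode: bool = True):
        for _, m in self.named_modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for mname, m in self.named_modules():
            for attr in m._state_attrs:
                key = f"{mname}.{attr}" if mname else attr
                state[key] = np.array(getattr(m, attr))
        return state

    def load_state_dict(self, state: dict[str, np.ndarray], strict: bool = True):
        own = dict(self.named_parameters())
        loaded = set()
        for name, p in own.items():
            if name in state:
                p.data = np.asarray(state[name], dtype=DTYPE).reshape(p.data.shape)
                loaded.add(name)
            elif strict:
                raise KeyError(f"missing parameter {name!r} in state")
        for mname, m in self.named_modules():
            for attr in m._state_attrs:
                key = f"{mname}.{attr}" if mname else attr
                if key in state:
                    setattr(m, attr, np.array(state[key]))
                    loaded.add(key)
                elif strict:
                    raise KeyError(f"missing state entry {key!r}")
        return loaded


def _fan_in_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = 1.0 / math.sqrt(max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape).astype(DTYPE)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        self.weight = Parameter(_fan_in_uniform(rng, (in_features, out_features), in_features))
        self.bias = Parameter(np.zeros(out_features, dtype=DTYPE)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(dim, dtype=DTYPE))
        self.beta = Parameter(np.zeros(dim, dtype=DTYPE))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc * ((var + self.eps) ** -0.5) * self.gamma + self.beta


class BatchNorm1d(Module):
    """Per-channel normalization of (B, C, T) over batch and time."""

    _state_attrs = ("running_mean", "running_var")

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.gamma = Parameter(np.ones(channels, dtype=DTYPE))
        self.beta = Parameter(np.zeros(channels, dtype=DTYPE))
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2), keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.ravel())
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data.ravel())
        else:
            mu = Tensor(self.running_mean.reshape(1, -1, 1))
            var = Tensor(self.running_var.reshape(1, -1, 1))
            xc = x - mu
        y = xc * ((var + self.eps) ** -0.5)
        return y * self.gamma.reshape(1, -1, 1) + self.beta.reshape(1, -1, 1)


class Conv1d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, groups: int = 1, bias: bool = True):
        super().__init__()
        if in_channels % groups or out_channels % groups:
            raise ValueError("channel counts must be divisible by groups")
        fan_in = (in_channels // groups) * kernel_size
        self.weight = Parameter(
            _fan_in_uniform(rng, (out_channels, in_channels // groups, kernel_size), fan_in))
        self.bias = Parameter(np.zeros(out_channels, dtype=DTYPE)) if bias else None
        self.groups = groups

    def __call__(self, x: Tensor) -> Tensor:
        return conv1d(x, self.weight, self.bias, groups=self.groups)


class Dropout(Module):
    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        self.rate = rate
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.rate <= 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape) < keep).astype(DTYPE) / keep
        return x * Tensor(mask)


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

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
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
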