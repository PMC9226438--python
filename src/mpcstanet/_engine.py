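"""Lightweight reverse-mode autodiff tensor engine on numpy.

Provides exactly the primitives the MPC-STANet architecture needs —
2-D convolution (with stride / padding / dilation), max and average
pooling, batch normalisation, linear layers, softmax cross-entropy and
the Adam optimizer — on plain ``numpy`` arrays.  Gradients of every
primitive are checked against central differences in the test suite.

Design notes
------------
* A :class:`Tensor` wraps an ``ndarray`` plus an optional gradient and a
  backward closure; :meth:`Tensor.backward` walks the recorded graph in
  reverse topological order.
* Convolution uses an im2col gather (a small python loop over the k×k
  kernel taps, each iteration a strided numpy slice) feeding one large
  matmul, which is where essentially all the time is spent.
* Everything is float32 by default; tests use float64 tensors for
  numerical gradient checks (ops preserve the input dtype).
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np

DEFAULT_DTYPE = np.float32


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional autodiff tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = (), _backward=None):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._prev = _prev
        self._backward = _backward

    # -- plumbing ---------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data, dtype=self.data.dtype)
        self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient needs a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; the graphs here are deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _needs(self, *others: "Tensor") -> bool:
        return self.requires_grad or any(o.requires_grad for o in others)

    # -- arithmetic -------------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _scalar_op(self, value, fn, grad_fn):
        # python scalars stay scalars (no float64 promotion) and need no graph node
        out = Tensor(fn(self.data, value), self.requires_grad, (self,))
        out._backward = lambda g: self.requires_grad and self._accum(grad_fn(g, value))
        return out

    def __add__(self, other):
        if isinstance(other, (int, float)):
            return self._scalar_op(other, lambda d, v: d + v, lambda g, v: g)
        other = self._lift(other)
        out = Tensor(self.data + other.data, self._needs(other), (self, other))

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, (self,))
        out._backward = lambda g: self.requires_grad and self._accum(-g)
        return out

    def __sub__(self, other):
        if isinstance(other, (int, float)):
            return self._scalar_op(other, lambda d, v: d - v, lambda g, v: g)
        return self + (-self._lift(other))

    def __rsub__(self, other):
        if isinstance(other, (int, float)):
            return self._scalar_op(other, lambda d, v: v - d, lambda g, v: -g)
        return self._lift(other) + (-self)

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            return self._scalar_op(other, lambda d, v: d * v, lambda g, v: g * v)
        other = self._lift(other)
        out = Tensor(self.data * other.data, self._needs(other), (self, other))

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return self._scalar_op(other, lambda d, v: d / v, lambda g, v: g / v)
        other = self._lift(other)
        out = Tensor(self.data / other.data, self._needs(other), (self, other))

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data**2, other.shape))

        out._backward = backward
        return out

    def __pow__(self, p: float):
        out = Tensor(self.data**p, self.requires_grad, (self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        out._backward = backward
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(np.matmul(self.data, other.data), self._needs(other), (self, other))

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(np.matmul(g, np.swapaxes(other.data, -1, -2)), self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(np.matmul(np.swapaxes(self.data, -1, -2), g), other.shape))

        out._backward = backward
        return out

    # -- reductions / shaping --------------------------------------------

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), self.requires_grad, (self,))

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).copy())

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else math.prod(
            self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), self.requires_grad, (self,))
        out._backward = lambda g: self.requires_grad and self._accum(g.reshape(self.shape))
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), self.requires_grad, (self,))
        out._backward = lambda g: self.requires_grad and self._accum(g.transpose(inv))
        return out

    def broadcast_to(self, shape):
        out = Tensor(np.broadcast_to(self.data, shape).copy(), self.requires_grad, (self,))
        out._backward = lambda g: self.requires_grad and self._accum(_unbroadcast(g, self.shape))
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], self.requires_grad, (self,))

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        out._backward = backward
        return out

    # -- elementwise nonlinearities --------------------------------------

    def exp(self):
        val = np.exp(self.data)
        out = Tensor(val, self.requires_grad, (self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * val)
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad, (self,))
        out._backward = lambda g: self.requires_grad and self._accum(g / self.data)
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, self.requires_grad, (self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * mask)
        return out

    def sigmoid(self):
        with np.errstate(over="ignore"):  # exp overflow saturates correctly
            val = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(val, self.requires_grad, (self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * val * (1.0 - val))
        return out


def maximum(a: Tensor, b: Tensor) -> Tensor:
    """Elementwise max; on ties the gradient routes to the first argument."""
    a, b = Tensor._lift(a), Tensor._lift(b)
    take_a = a.data >= b.data
    out = Tensor(np.where(take_a, a.data, b.data), a._needs(b), (a, b))

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * take_a, a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * ~take_a, b.shape))

    out._backward = backward
    return out


def concatenate(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        any(t.requires_grad for t in tensors),
        tuple(tensors),
    )
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    out._backward = backward
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))  # detached max for stability
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


# ---------------------------------------------------------------------------
# convolution / pooling primitives
# ---------------------------------------------------------------------------


def conv_out_len(w_in: int, k: int, stride: int, pad: int, dilation: int) -> int:
    return (w_in + 2 * pad - dilation * (k - 1) - 1) // stride + 1


def _im2col(x: np.ndarray, kh, kw, sh, sw, ph, pw, dh, dw):
    n, c, h, w = x.shape
    ho = conv_out_len(h, kh, sh, ph, dh)
    wo = conv_out_len(w, kw, sw, pw, dw)
    if ho < 1 or wo < 1:
        raise ValueError("kernel larger than padded input")
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw))) if (ph or pw) else x
    cols = np.empty((n, c, kh, kw, ho, wo), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = xp[:, :, i * dh : i * dh + sh * ho : sh, j * dw : j * dw + sw * wo : sw]
    return cols, ho, wo


def _col2im(dcols: np.ndarray, x_shape, kh, kw, sh, sw, ph, pw, dh, dw, ho, wo):
    n, c, h, w = x_shape
    gxp = np.zeros((n, c, h + 2 * ph, w + 2 * pw), dtype=dcols.dtype)
    for i in range(kh):
        for j in range(kw):
            gxp[:, :, i * dh : i * dh + sh * ho : sh, j * dw : j * dw + sw * wo : sw] += dcols[:, :, i, j]
    if ph or pw:
        return gxp[:, :, ph : ph + h, pw : pw + w]
    return gxp


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int = 0, dilation: int = 1) -> Tensor:
    """2-D convolution, NCHW, square kernel/stride/padding/dilation."""
    o, cin, kh, kw = weight.shape
    cols, ho, wo = _im2col(x.data, kh, kw, stride, stride, padding, padding, dilation, dilation)
    n = x.shape[0]
    cols2 = cols.reshape(n, cin * kh * kw, ho * wo)
    wmat = weight.data.reshape(o, cin * kh * kw)
    out_data = np.matmul(wmat, cols2).reshape(n, o, ho, wo)
    if bias is not None:
        out_data = out_data + bias.data.reshape(1, o, 1, 1)
    prev = (x, weight) if bias is None else (x, weight, bias)
    out = Tensor(out_data, x._needs(weight) or (bias is not None and bias.requires_grad), prev)

    def backward(g):
        gmat = g.reshape(n, o, ho * wo)
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))
        if weight.requires_grad:
            dw = np.einsum("nop,ncp->oc", gmat, cols2, optimize=True)
            weight._accum(dw.reshape(weight.shape))
        if x.requires_grad:
            dcols = np.matmul(wmat.T, gmat)  # (n, cin*kh*kw, ho*wo)
            dcols = dcols.reshape(n, cin, kh, kw, ho, wo)
            x._accum(_col2im(dcols, x.shape, kh, kw, stride, stride,
                             padding, padding, dilation, dilation, ho, wo))

    out._backward = backward
    return out


def max_pool2d(x: Tensor, kernel: int, stride: int, padding: int = 0) -> Tensor:
    if padding:
        # pad with -inf: zero padding would beat negative activations
        xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                    constant_values=-np.inf)
        cols, ho, wo = _im2col(xp, kernel, kernel, stride, stride, 0, 0, 1, 1)
    else:
        cols, ho, wo = _im2col(x.data, kernel, kernel, stride, stride, 0, 0, 1, 1)
    n, c = x.shape[:2]
    flat = cols.reshape(n, c, kernel * kernel, ho, wo)
    arg = flat.argmax(axis=2)
    out_data = np.take_along_axis(flat, arg[:, :, None], axis=2)[:, :, 0]
    out = Tensor(out_data, x.requires_grad, (x,))

    def backward(g):
        if not x.requires_grad:
            return
        dcols = np.zeros_like(flat)
        np.put_along_axis(dcols, arg[:, :, None], g[:, :, None], axis=2)
        dcols = dcols.reshape(n, c, kernel, kernel, ho, wo)
        x._accum(_col2im(dcols, x.shape, kernel, kernel, stride, stride,
                         padding, padding, 1, 1, ho, wo))

    out._backward = backward
    return out


def avg_pool2d(x: Tensor, kernel: int, stride: int, padding: int = 0) -> Tensor:
    cols, ho, wo = _im2col(x.data, kernel, kernel, stride, stride, padding, padding, 1, 1)
    n, c = x.shape[:2]
    flat = cols.reshape(n, c, kernel * kernel, ho, wo)
    out = Tensor(flat.mean(axis=2), x.requires_grad, (x,))

    def backward(g):
        if not x.requires_grad:
            return
        dcols = np.broadcast_to(g[:, :, None] / (kernel * kernel),
                                (n, c, kernel * kernel, ho, wo))
        dcols = dcols.reshape(n, c, kernel, kernel, ho, wo)
        x._accum(_col2im(np.ascontiguousarray(dcols), x.shape, kernel, kernel,
                         stride, stride, padding, padding, 1, 1, ho, wo))

    out._backward = backward
    return out


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------


class Module:
    """Minimal module base: parameter registry and train/eval mode."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, Module] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def register_parameter(self, name: str, tensor: Tensor) -> Tensor:
        tensor.requires_grad = True
        self._params[name] = tensor
        object.__setattr__(self, name, tensor)
        return tensor

    def parameters(self) -> Iterable[Tensor]:
        for p in self._params.values():
            yield p
        for m in self._modules.values():
            yield from m.parameters()

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield (f"{prefix}{name}", p)
        for mname, m in self._modules.items():
            yield from m.named_parameters(prefix=f"{prefix}{mname}.")

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {}
        for name, p in self._params.items():
            out[f"{prefix}{name}"] = p.data
        for battr in ("running_mean", "running_var"):
            if battr in self.__dict__ and isinstance(self.__dict__[battr], np.ndarray):
                out[f"{prefix}{battr}"] = self.__dict__[battr]
        for mname, m in self._modules.items():
            out.update(m.state_dict(prefix=f"{prefix}{mname}."))
        return out

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for name, p in self._params.items():
            p.data = np.array(state[f"{prefix}{name}"], dtype=p.data.dtype)
        for battr in ("running_mean", "running_var"):
            key = f"{prefix}{battr}"
            if key in state and battr in self.__dict__:
                object.__setattr__(self, battr, np.array(state[key]))
        for mname, m in self._modules.items():
            m.load_state_dict(state, prefix=f"{prefix}{mname}.")


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, dilation: int = 1,
                 bias: bool = False, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.stride, self.padding, self.dilation = stride, padding, dilation
        self.in_channels, self.out_channels, self.kernel_size = in_channels, out_channels, kernel_size
        # Kaiming normal, fan-out mode, as is conventional before BN+ReLU
        fan_out = out_channels * kernel_size * kernel_size
        w = rng.normal(0.0, math.sqrt(2.0 / fan_out),
                       size=(out_channels, in_channels, kernel_size, kernel_size))
        self.register_parameter("weight", Tensor(w.astype(DEFAULT_DTYPE)))
        if bias:
            self.register_parameter("bias", Tensor(np.zeros(out_channels, dtype=DEFAULT_DTYPE)))
        else:
            object.__setattr__(self, "bias", None)

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding, self.dilation)


class BatchNorm2d(Module):
    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum, self.num_features = eps, momentum, num_features
        self.register_parameter("weight", Tensor(np.ones(num_features, dtype=DEFAULT_DTYPE)))
        self.register_parameter("bias", Tensor(np.zeros(num_features, dtype=DEFAULT_DTYPE)))
        object.__setattr__(self, "running_mean", np.zeros(num_features, dtype=DEFAULT_DTYPE))
        object.__setattr__(self, "running_var", np.ones(num_features, dtype=DEFAULT_DTYPE))

    def forward(self, x: Tensor) -> Tensor:
        # fused primitive: the closed-form batch-norm gradient avoids a
        # long chain of full-size elementwise autodiff temporaries
        c = self.num_features
        gamma, beta = self.weight, self.bias
        axes = (0, 2, 3)
        if self.training:
            mu = x.data.mean(axis=axes)
            var = x.data.var(axis=axes)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mu).astype(self.running_mean.dtype)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(self.running_var.dtype)
        else:
            mu = self.running_mean.astype(x.dtype.type)
            var = self.running_var.astype(x.dtype.type)
        inv_std = (1.0 / np.sqrt(var + self.eps)).astype(x.dtype.type)
        xhat = (x.data - mu[None, :, None, None]) * inv_std[None, :, None, None]
        out_data = xhat * gamma.data[None, :, None, None] + beta.data[None, :, None, None]
        out = Tensor(out_data, x._needs(gamma, beta), (x, gamma, beta))
        training = self.training

        def backward(g):
            if gamma.requires_grad:
                gamma._accum((g * xhat).sum(axis=axes))
            if beta.requires_grad:
                beta._accum(g.sum(axis=axes))
            if not x.requires_grad:
                return
            scale = (gamma.data * inv_std)[None, :, None, None]
            if training:
                nhw = g.shape[0] * g.shape[2] * g.shape[3]
                g_mean = g.mean(axis=axes)[None, :, None, None]
                gx_mean = (g * xhat).sum(axis=axes)[None, :, None, None] / nhw
                x._accum(scale * (g - g_mean - xhat * gx_mean))
            else:
                x._accum(scale * g)

        out._backward = backward
        return out


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        bound = 1.0 / math.sqrt(in_features)
        w = rng.uniform(-bound, bound, size=(out_features, in_features))
        self.register_parameter("weight", Tensor(w.astype(DEFAULT_DTYPE)))
        if bias:
            b = rng.uniform(-bound, bound, size=out_features)
            self.register_parameter("bias", Tensor(b.astype(DEFAULT_DTYPE)))
        else:
            object.__setattr__(self, "bias", None)

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight.transpose(1, 0)
        if self.bias is not None:
            out = out + self.bias
        return out


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class MaxPool2d(Module):
    def __init__(self, kernel_size: int, stride: int, padding: int = 0):
        super().__init__()
        self.kernel_size, self.stride, self.padding = kernel_size, stride, padding

    def forward(self, x: Tensor) -> Tensor:
        return max_pool2d(x, self.kernel_size, self.stride, self.padding)


class AvgPool2d(Module):
    def __init__(self, kernel_size: int, stride: int, padding: int = 0):
        super().__init__()
        self.kernel_size, self.stride, self.padding = kernel_size, stride, padding

    def forward(self, x: Tensor) -> Tensor:
        return avg_pool2d(x, self.kernel_size, self.stride, self.padding)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            self._modules[str(i)] = layer

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


def softmax_cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer ``targets`` under softmax of ``logits``."""
    n, k = logits.shape
    shifted = logits - Tensor(logits.data.max(axis=1, keepdims=True))
    logz = shifted.exp().sum(axis=1, keepdims=True).log()
    logp = shifted - logz
    onehot = np.zeros((n, k), dtype=logits.data.dtype)
    onehot[np.arange(n), np.asarray(targets)] = 1.0
    return -(logp * Tensor(onehot)).sum() * (1.0 / n)


class Adam:
    """Adaptive-moment optimizer with the canonical published defaults."""

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
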