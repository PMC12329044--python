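"""Minimal reverse-mode automatic differentiation over numpy arrays.

The reconstruction network (encoder, 3D convolutional LSTM, decoder) is trained
jointly by gradient descent, so every building block here carries its own
backward rule.  The op set is deliberately small: elementwise arithmetic with
broadcasting, matmul, reshape/transpose/slicing/padding, reductions, the
sigmoid/tanh/LeakyReLU nonlinearities, and dedicated 2-D / depthwise-2-D / 3-D
convolution and nearest-neighbour 3-D unpooling primitives implemented with
sliding-window views so the heavy lifting stays inside BLAS.

All tensors are float64; computation is deterministic for a fixed seed and
thread count.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "sigmoid",
    "tanh",
    "leaky_relu",
    "conv2d",
    "depthwise_conv2d",
    "conv3d",
    "unpool3d",
    "Adam",
    "he_uniform",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
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
    """A node in the computation graph: a float64 array plus a backward rule."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    # -- basic protocol ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- graph construction helpers ---------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        if any(p.requires_grad for p in parents):
            return Tensor(data, parents=parents, backward=backward)
        return Tensor(data)

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out_data = self.data / other.data

        def backward(g):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            )

        return self._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, exponent: float):
        out_data = self.data**exponent

        def backward(g):
            return (g * exponent * self.data ** (exponent - 1),)

        return self._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = self._lift(other)
        out_data = self.data @ other.data

        def backward(g):
            ga = g @ np.swapaxes(other.data, -1, -2)
            gb = np.swapaxes(self.data, -1, -2) @ g
            return (_unbroadcast(ga, self.shape), _unbroadcast(gb, other.shape))

        return self._make(out_data, (self, other), backward)

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        return self._make(
            self.data.reshape(shape), (self,), lambda g: (g.reshape(old),)
        )

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = tuple(np.argsort(axes))
        return self._make(
            self.data.transpose(axes), (self,), lambda g: (g.transpose(inv),)
        )

    def __getitem__(self, idx):
        out_data = self.data[idx]
        shape = self.shape

        def backward(g):
            gx = np.zeros(shape, dtype=np.float64)
            gx[idx] += g
            return (gx,)

        return self._make(out_data, (self,), backward)

    def pad(self, pad_width):
        """Zero padding; ``pad_width`` as for np.pad."""
        out_data = np.pad(self.data, pad_width)
        slices = tuple(
            slice(lo, lo + n) for (lo, _), n in zip(pad_width, self.shape)
        )
        return self._make(out_data, (self,), lambda g: (g[slices],))

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.shape

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, shape).copy(),)
            ax = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                g = np.expand_dims(g, ax)
            return (np.broadcast_to(g, shape).copy(),)

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- elementwise functions ---------------------------------------------
    def log(self):
        return self._make(np.log(self.data), (self,), lambda g: (g / self.data,))

    def exp(self):
        out_data = np.exp(self.data)
        return self._make(out_data, (self,), lambda g: (g * out_data,))

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes through only where not clipped."""
        out_data = np.clip(self.data, lo, hi)
        inside = (self.data > lo) & (self.data < hi)
        return self._make(out_data, (self,), lambda g: (g * inside,))

    # -- backward pass -----------------------------------------------------
    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient on non-scalar tensor")
            grad = np.ones_like(self.data)

        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
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

        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is None:
                continue
            parent_grads = node._backward(g)
            for p, pg in zip(node._parents, parent_grads):
                if not p.requires_grad or pg is None:
                    continue
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg


class Parameter(Tensor):
    """A leaf tensor that accumulates gradients and is updated by optimizers."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def sigmoid(x: Tensor) -> Tensor:
    out_data = 1.0 / (1.0 + np.exp(-x.data))
    return x._make(out_data, (x,), lambda g: (g * out_data * (1.0 - out_data),))


def tanh(x: Tensor) -> Tensor:
    out_data = np.tanh(x.data)
    return x._make(out_data, (x,), lambda g: (g * (1.0 - out_data**2),))


def leaky_relu(x: Tensor, slope: float = 0.1) -> Tensor:
    factor = np.where(x.data >= 0, 1.0, slope)
    return x._make(x.data * factor, (x,), lambda g: (g * factor,))


# ---------------------------------------------------------------------------
# Convolution primitives
# ---------------------------------------------------------------------------


def _windows2d(x: np.ndarray, k: int, stride: int) -> np.ndarray:
    """(B,C,H,W) -> (B,C,Ho,Wo,k,k) sliding windows with the given stride."""
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    return win[:, :, ::stride, ::stride]


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, pad: int = 0) -> Tensor:
    """2-D cross-correlation. x:(B,Ci,H,W), w:(Co,Ci,k,k), b:(Co,) -> (B,Co,Ho,Wo)."""
    k = w.shape[-1]
    xp = x.pad(((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x
    xd = xp.data
    win = _windows2d(xd, k, stride)  # B,Ci,Ho,Wo,k,k
    out_data = np.tensordot(win, w.data, axes=([1, 4, 5], [1, 2, 3]))  # B,Ho,Wo,Co
    out_data = np.ascontiguousarray(out_data.transpose(0, 3, 1, 2))
    B, Co, Ho, Wo = out_data.shape

    def backward(g):
        # g: (B,Co,Ho,Wo)
        gw = np.tensordot(g, win, axes=([0, 2, 3], [0, 2, 3]))  # Co,Ci,k,k
        gcols = np.tensordot(g, w.data, axes=(1, 0))  # B,Ho,Wo,Ci,k,k
        gx = np.zeros_like(xd)
        for u in range(k):
            for v in range(k):
                gx[:, :, u : u + Ho * stride : stride, v : v + Wo * stride : stride] += (
                    gcols[:, :, :, :, u, v].transpose(0, 3, 1, 2)
                )
        return (gx, gw)

    out = Tensor(out_data, parents=(xp, w), backward=backward)
    if b is not None:
        out = out + b.reshape(1, -1, 1, 1)
    return out


def depthwise_conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, pad: int = 0) -> Tensor:
    """Per-channel 2-D convolution. x:(B,C,H,W), w:(C,k,k) -> (B,C,Ho,Wo)."""
    k = w.shape[-1]
    xp = x.pad(((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x
    xd = xp.data
    win = _windows2d(xd, k, stride)  # B,C,Ho,Wo,k,k
    out_data = np.einsum("bchwuv,cuv->bchw", win, w.data, optimize=True)
    B, C, Ho, Wo = out_data.shape

    def backward(g):
        gw = np.einsum("bchw,bchwuv->cuv", g, win, optimize=True)
        gx = np.zeros_like(xd)
        for u in range(k):
            for v in range(k):
                gx[:, :, u : u + Ho * stride : stride, v : v + Wo * stride : stride] += (
                    g * w.data[None, :, u, v, None, None]
                )
        return (gx, gw)

    out = Tensor(out_data, parents=(xp, w), backward=backward)
    if b is not None:
        out = out + b.reshape(1, -1, 1, 1)
    return out


def conv3d(x: Tensor, w: Tensor, b: Tensor | None, pad: int | None = None) -> Tensor:
    """Same-size 3-D cross-correlation over a voxel grid.

    x:(B,Ci,D,H,W), w:(Co,Ci,k,k,k), b:(Co,) -> (B,Co,D,H,W); zero padding
    defaults to k//2 so spatial size is preserved (stride 1).
    """
    k = w.shape[-1]
    if pad is None:
        pad = k // 2
    xp = x.pad(((0, 0), (0, 0), (pad, pad), (pad, pad), (pad, pad))) if pad else x
    xd = xp.data
    win = np.lib.stride_tricks.sliding_window_view(xd, (k, k, k), axis=(2, 3, 4))
    # win: B,Ci,Do,Ho,Wo,k,k,k
    out_data = np.tensordot(win, w.data, axes=([1, 5, 6, 7], [1, 2, 3, 4]))
    out_data = np.ascontiguousarray(out_data.transpose(0, 4, 1, 2, 3))
    B, Co, Do, Ho, Wo = out_data.shape

    def backward(g):
        gw = np.tensordot(g, win, axes=([0, 2, 3, 4], [0, 2, 3, 4]))
        gcols = np.tensordot(g, w.data, axes=(1, 0))  # B,Do,Ho,Wo,Ci,k,k,k
        gx = np.zeros_like(xd)
        for u in range(k):
            for v in range(k):
                for t in range(k):
                    gx[:, :, u : u + Do, v : v + Ho, t : t + Wo] += gcols[
                        :, :, :, :, :, u, v, t
                    ].transpose(0, 4, 1, 2, 3)
        return (gx, gw)

    out = Tensor(out_data, parents=(xp, w), backward=backward)
    if b is not None:
        out = out + b.reshape(1, -1, 1, 1, 1)
    return out


def unpool3d(x: Tensor, factor: int) -> Tensor:
    """Nearest-neighbour unpooling: each cell becomes a factor^3 block.

    x:(..., D,H,W) -> (..., f*D, f*H, f*W).
    """
    if int(factor) != factor or factor < 1:
        raise ValueError("unpool factor must be a positive integer")
    f = int(factor)
    xd = x.data
    out_data = xd.repeat(f, axis=-3).repeat(f, axis=-2).repeat(f, axis=-1)
    lead = xd.shape[:-3]
    D, H, W = xd.shape[-3:]

    def backward(g):
        g6 = g.reshape(lead + (D, f, H, f, W, f))
        return (g6.sum(axis=(-5, -3, -1)),)

    return x._make(out_data, (x,), backward)


# ---------------------------------------------------------------------------
# Initialisation and optimisation
# ---------------------------------------------------------------------------


def he_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    limit = np.sqrt(6.0 / max(fan_in, 1))
    return rng.uniform(-limit, limit, size=shape)


class Adam:
    """Adam optimizer with optional global-norm gradient clipping."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8, clip_norm: float | None = None):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        grads = [p.grad if p.grad is not None else np.zeros_like(p.data)
                 for p in self.params]
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((g**2).sum()) for g in grads))
            if total > self.clip_norm:
                scale = self.clip_norm / (total + 1e-12)
                grads = [g * scale for g in grads]
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
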