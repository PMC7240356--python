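"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Provides exactly the operator set the image-translation networks need:
elementwise arithmetic, reductions, activations, channel concatenation,
stride-1 "same" convolution (via im2col), 2x average pooling and 2x
nearest-neighbour upsampling, plus a numerically stable binary
cross-entropy on logits.  Gradients flow through a topologically sorted
tape.  Everything is float32.
"""

from __future__ import annotations

import numpy as np

_F = np.float32


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=_F)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    # -- graph construction -------------------------------------------------

    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        # reverse numpy broadcasting
        g = np.asarray(g, dtype=_F)
        extra = g.ndim - self.data.ndim
        if extra > 0:
            g = g.sum(axis=tuple(range(extra)))
        for ax, n in enumerate(self.data.shape):
            if n == 1 and g.shape[ax] != 1:
                g = g.sum(axis=ax, keepdims=True)
        self.grad += g

    def backward(self):
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None:
                node._backward(node.grad)

    # -- arithmetic ---------------------------------------------------------

    def _coerce(self, other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        o = self._coerce(other)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g)
            if o.requires_grad:
                o._accumulate(g)

        return Tensor._make(self.data + o.data, (self, o), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            self._accumulate(-g)

        return Tensor._make(-self.data, (self,), bwd)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        o = self._coerce(other)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * o.data)
            if o.requires_grad:
                o._accumulate(g * self.data)

        return Tensor._make(self.data * o.data, (self, o), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = self._coerce(other)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g / o.data)
            if o.requires_grad:
                o._accumulate(-g * self.data / (o.data * o.data))

        return Tensor._make(self.data / o.data, (self, o), bwd)

    # -- reductions ---------------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            gg = np.asarray(g, dtype=_F)
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accumulate(np.broadcast_to(gg, self.data.shape))

        return Tensor._make(data, (self,), bwd)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- elementwise functions ----------------------------------------------

    def abs(self):
        def bwd(g):
            self._accumulate(g * np.sign(self.data))

        return Tensor._make(np.abs(self.data), (self,), bwd)

    def sqrt(self):
        data = np.sqrt(self.data)

        def bwd(g):
            self._accumulate(g * 0.5 / np.maximum(data, 1e-12))

        return Tensor._make(data, (self,), bwd)

    def tanh(self):
        data = np.tanh(self.data)

        def bwd(g):
            self._accumulate(g * (1.0 - data * data))

        return Tensor._make(data, (self,), bwd)

    def relu(self):
        mask = self.data > 0

        def bwd(g):
            self._accumulate(g * mask)

        return Tensor._make(self.data * mask, (self,), bwd)

    def leaky_relu(self, slope: float = 0.2):
        factor = np.where(self.data > 0, _F(1.0), _F(slope))

        def bwd(g):
            self._accumulate(g * factor)

        return Tensor._make(self.data * factor, (self,), bwd)

    def reshape(self, *shape):
        old = self.data.shape

        def bwd(g):
            self._accumulate(g.reshape(old))

        return Tensor._make(self.data.reshape(*shape), (self,), bwd)


# ---------------------------------------------------------------------------
# spatial ops on (N, C, H, W) tensors
# ---------------------------------------------------------------------------


def concat_channels(a: Tensor, b: Tensor) -> Tensor:
    ca = a.data.shape[1]

    def bwd(g):
        if a.requires_grad:
            a._accumulate(g[:, :ca])
        if b.requires_grad:
            b._accumulate(g[:, ca:])

    return Tensor._make(np.concatenate([a.data, b.data], axis=1), (a, b), bwd)


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """Extract kxk sliding windows of a padded (N,C,Hp,Wp) array as
    (N*H*W, C*k*k) with stride 1."""
    n, c, hp, wp = x.shape
    h, w = hp - k + 1, wp - k + 1
    s0, s1, s2, s3 = x.strides
    view = np.lib.stride_tricks.as_strided(
        x, (n, c, k, k, h, w), (s0, s1, s2, s3, s2, s3)
    )
    return view.transpose(0, 4, 5, 1, 2, 3).reshape(n * h * w, c * k * k)


def conv2d(x: Tensor, weight: Tensor, bias: Tensor, k: int) -> Tensor:
    """Stride-1 'same' 2-D convolution (cross-correlation).

    ``weight`` has shape (out_ch, in_ch, k, k); ``bias`` shape (out_ch,).
    Odd ``k`` only; output spatial shape equals the input's.
    """
    pad = k // 2
    n, c, h, w = x.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = _im2col(xp, k)  # (N*H*W, C*k*k)
    wmat = weight.data.reshape(weight.data.shape[0], -1)  # (O, C*k*k)
    out = cols @ wmat.T + bias.data
    o = weight.data.shape[0]
    out = out.reshape(n, h, w, o).transpose(0, 3, 1, 2)

    def bwd(g):
        g2 = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(n * h * w, o)
        if bias.requires_grad:
            bias._accumulate(g2.sum(axis=0))
        if weight.requires_grad:
            weight._accumulate((g2.T @ cols).reshape(weight.data.shape))
        if x.requires_grad:
            dcols = (g2 @ wmat).reshape(n, h, w, c, k, k)
            dxp = np.zeros_like(xp)
            for i in range(k):
                for j in range(k):
                    dxp[:, :, i : i + h, j : j + w] += dcols[
                        :, :, :, :, i, j
                    ].transpose(0, 3, 1, 2)
            x._accumulate(dxp[:, :, pad : pad + h, pad : pad + w]
                          if pad else dxp)

    return Tensor._make(out, (x, weight, bias), bwd)


def avg_pool2(x: Tensor) -> Tensor:
    """2x2 average pooling (spatial dims must be even)."""
    n, c, h, w = x.data.shape
    v = x.data.reshape(n, c, h // 2, 2, w // 2, 2)
    out = v.mean(axis=(3, 5))

    def bwd(g):
        gx = np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) * 0.25
        x._accumulate(gx)

    return Tensor._make(out, (x,), bwd)


def upsample2(x: Tensor) -> Tensor:
    """2x nearest-neighbour upsampling."""
    out = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)

    def bwd(g):
        n, c, h2, w2 = g.shape
        gx = g.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5))
        x._accumulate(gx)

    return Tensor._make(out, (x,), bwd)


def bce_with_logits(logits: Tensor, target: float) -> Tensor:
    """Mean binary cross-entropy against a constant 0/1 target.

    Computed as mean(softplus(z) - t*z), which is stable for large |z|.
    """
    z = logits.data
    data = np.mean(np.logaddexp(0.0, z) - target * z)

    def bwd(g):
        sig = 1.0 / (1.0 + np.exp(-z))
        logits._accumulate(g * (sig - target) / z.size)

    return Tensor._make(data, (logits,), bwd)
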