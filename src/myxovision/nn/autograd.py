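"""Minimal reverse-mode automatic differentiation over numpy arrays.

Only the operations needed by the image-translation networks are provided:
broadcast-aware elementwise arithmetic, reductions, activations, 2-D
convolution (im2col), nearest-neighbor upsampling, 2×2 average pooling,
reflection padding, and channel concatenation.  Gradients are accumulated by
a topological-order sweep from the loss.  Every operation is gradient-checked
against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd_extra = grad.ndim - len(shape)
    if nd_extra > 0:
        grad = grad.sum(axis=tuple(range(nd_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- construction helpers ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _make(self, data, prev, backward) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in prev)
        if out.requires_grad:
            out._prev = tuple(prev)
            out._backward = backward
        return out

    # -- arithmetic ----------------------------------------------------------
    @staticmethod
    def _coerce(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._coerce(other)
        out_data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        out_data = self.data * other.data

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __pow__(self, exponent: float):
        out_data = self.data ** exponent

        def backward(g):
            return (g * exponent * self.data ** (exponent - 1.0),)

        return self._make(out_data, (self,), backward)

    def __truediv__(self, other):
        return self * (self._coerce(other) ** -1.0)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- activations ---------------------------------------------------------
    def relu(self):
        mask = self.data > 0
        return self._make(self.data * mask, (self,), lambda g: (g * mask,))

    def leaky_relu(self, slope: float = 0.2):
        factor = np.where(self.data > 0, 1.0, slope)
        return self._make(self.data * factor, (self,), lambda g: (g * factor,))

    def tanh(self):
        out_data = np.tanh(self.data)
        return self._make(out_data, (self,), lambda g: (g * (1 - out_data**2),))

    def abs(self):
        sign = np.sign(self.data)
        return self._make(np.abs(self.data), (self,), lambda g: (g * sign,))

    # -- shape ---------------------------------------------------------------
    def reshape(self, *shape):
        orig = self.shape
        return self._make(
            self.data.reshape(*shape), (self,), lambda g: (g.reshape(orig),)
        )

    @staticmethod
    def concat(tensors: list["Tensor"], axis: int = 1) -> "Tensor":
        tensors = [Tensor._coerce(t) for t in tensors]
        out_data = np.concatenate([t.data for t in tensors], axis=axis)
        sizes = [t.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def backward(g):
            return tuple(np.split(g, splits, axis=axis))

        dummy = tensors[0]
        return dummy._make(out_data, tensors, backward)

    # -- image ops -----------------------------------------------------------
    def pad2d_reflect(self, pad: int):
        """Reflection-pad the last two axes by ``pad`` on each side."""
        if pad == 0:
            return self
        n = self.shape[-1]
        m = self.shape[-2]
        ridx = np.pad(np.arange(m), pad, mode="reflect")
        cidx = np.pad(np.arange(n), pad, mode="reflect")
        out_data = self.data[..., ridx[:, None], cidx[None, :]]

        def backward(g):
            dx = np.zeros(self.shape)
            np.add.at(dx, (..., ridx[:, None], cidx[None, :]), g)
            return (dx,)

        return self._make(out_data, (self,), backward)

    def pad2d_zero(self, pad: int):
        if pad == 0:
            return self
        widths = [(0, 0)] * (self.data.ndim - 2) + [(pad, pad), (pad, pad)]
        out_data = np.pad(self.data, widths)
        sl = (Ellipsis, slice(pad, -pad), slice(pad, -pad))
        return self._make(out_data, (self,), lambda g: (g[sl],))

    def upsample_nearest(self, factor: int = 2):
        out_data = self.data.repeat(factor, axis=-2).repeat(factor, axis=-1)
        n, c, h, w = self.shape

        def backward(g):
            return (
                g.reshape(n, c, h, factor, w, factor).sum(axis=(3, 5)),
            )

        return self._make(out_data, (self,), backward)

    def avg_pool2(self):
        n, c, h, w = self.shape
        if h % 2 or w % 2:
            raise ValueError("avg_pool2 requires even spatial dimensions")
        out_data = self.data.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

        def backward(g):
            return (g.repeat(2, axis=-2).repeat(2, axis=-1) / 4.0,)

        return self._make(out_data, (self,), backward)

    def conv2d(self, weight: "Tensor", bias: "Tensor", stride: int = 1):
        """Valid-mode 2-D convolution (cross-correlation) via im2col.

        ``self``: (N, C, H, W); ``weight``: (O, C, kh, kw); ``bias``: (O,).
        Pad beforehand with ``pad2d_zero`` / ``pad2d_reflect``.
        """
        x = self.data
        n, c, h, w = x.shape
        o, c2, kh, kw = weight.shape
        if c != c2:
            raise ValueError("channel mismatch in conv2d")
        oh = (h - kh) // stride + 1
        ow = (w - kw) // stride + 1
        if oh < 1 or ow < 1:
            raise ValueError("kernel larger than input in conv2d")
        s0, s1, s2, s3 = x.strides
        patches = np.lib.stride_tricks.as_strided(
            x, (n, c, kh, kw, oh, ow), (s0, s1, s2, s3, s2 * stride, s3 * stride)
        )
        # reshaping the strided view copies into contiguous memory
        cols = np.ascontiguousarray(patches).reshape(n, c * kh * kw, oh * ow)
        wmat = weight.data.reshape(o, c * kh * kw)
        out_data = np.einsum("ok,nkl->nol", wmat, cols).reshape(n, o, oh, ow)
        out_data += bias.data.reshape(1, o, 1, 1)

        def backward(g):
            gmat = g.reshape(n, o, oh * ow)
            dW = np.einsum("nol,nkl->ok", gmat, cols).reshape(weight.shape)
            db = g.sum(axis=(0, 2, 3))
            dcols = np.einsum("ok,nol->nkl", wmat, gmat)
            dcols = dcols.reshape(n, c, kh, kw, oh, ow)
            dx = np.zeros_like(x)
            for i in range(kh):
                for j in range(kw):
                    dx[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride] += \
                        dcols[:, :, i, j]
            return (dx, dW, db)

        return self._make(out_data, (self, weight, bias), backward)

    # -- backward sweep ------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._prev, grads):
                if not parent.requires_grad or g is None:
                    continue
                if parent.grad is None:
                    parent.grad = np.asarray(g, dtype=np.float64).copy()
                else:
                    parent.grad += g
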