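"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just enough machinery to train a small convolutional detector on CPU:
broadcast-aware elementwise ops, matmul, im2col convolution, pooling
reductions, and a topological-sort backward pass.  Convolutions are lowered
to BLAS matmuls via im2col, which is where essentially all training time is
spent.  Gradient correctness is pinned down by finite-difference tests.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "conv2d", "upsample2x", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a broadcast gradient back down to the original operand shape."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus the tape entry needed to backpropagate through it."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        data = np.asarray(data)
        if data.dtype not in (np.float32, np.float64):
            data = data.astype(np.float32)
        self.data = data
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _from_op(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- elementwise arithmetic ----------------------------------------------

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def backward(grad):
            return _unbroadcast(grad, self.shape), _unbroadcast(grad, other.shape)

        return Tensor._from_op(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._from_op(-self.data, (self,), lambda grad: (-grad,))

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out_data = self.data * other.data

        def backward(grad):
            return (
                _unbroadcast(grad * other.data, self.shape),
                _unbroadcast(grad * self.data, other.shape),
            )

        return Tensor._from_op(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        out_data = self.data / other.data

        def backward(grad):
            return (
                _unbroadcast(grad / other.data, self.shape),
                _unbroadcast(-grad * self.data / (other.data**2), other.shape),
            )

        return Tensor._from_op(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, exponent: float):
        out_data = self.data**exponent

        def backward(grad):
            return (grad * exponent * self.data ** (exponent - 1),)

        return Tensor._from_op(out_data, (self,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)
        out_data = self.data @ other.data

        def backward(grad):
            return grad @ other.data.T, self.data.T @ grad

        return Tensor._from_op(out_data, (self, other), backward)

    # -- nonlinearities -------------------------------------------------------

    def relu(self):
        mask = self.data > 0
        return Tensor._from_op(self.data * mask, (self,), lambda grad: (grad * mask,))

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(grad):
            return (grad * out_data * (1.0 - out_data),)

        return Tensor._from_op(out_data, (self,), backward)

    def log(self):
        def backward(grad):
            return (grad / self.data,)

        return Tensor._from_op(np.log(self.data), (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)
        return Tensor._from_op(out_data, (self,), lambda grad: (grad * out_data,))

    def sqrt(self):
        out_data = np.sqrt(self.data)
        return Tensor._from_op(out_data, (self,), lambda grad: (grad * 0.5 / out_data,))

    def abs(self):
        sign = np.sign(self.data)
        return Tensor._from_op(np.abs(self.data), (self,), lambda grad: (grad * sign,))

    def clamp(self, lo: float, hi: float):
        """Clip values; gradient passes only where the input was in range."""
        mask = (self.data >= lo) & (self.data <= hi)
        return Tensor._from_op(np.clip(self.data, lo, hi), (self,), lambda grad: (grad * mask,))

    # -- reductions and shape ops ---------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(grad):
            g = np.asarray(grad)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)

        return Tensor._from_op(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        count = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(count))

    def max(self, axis: int, keepdims: bool = False):
        out_data = self.data.max(axis=axis, keepdims=keepdims)
        argmax = np.expand_dims(self.data.argmax(axis=axis), axis)

        def backward(grad):
            g = np.asarray(grad)
            if not keepdims:
                g = np.expand_dims(g, axis)
            out = np.zeros_like(self.data)
            np.put_along_axis(out, argmax, g, axis=axis)
            return (out,)

        return Tensor._from_op(out_data, (self,), backward)

    def reshape(self, *shape):
        old_shape = self.shape
        return Tensor._from_op(
            self.data.reshape(*shape), (self,), lambda grad: (grad.reshape(old_shape),)
        )

    def transpose(self, *axes):
        inverse = np.argsort(axes)
        return Tensor._from_op(
            self.data.transpose(*axes), (self,), lambda grad: (grad.transpose(*inverse),)
        )

    # -- backward pass --------------------------------------------------------

    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for parent in node._parents:
                if parent.requires_grad and id(parent) not in visited:
                    stack.append((parent, False))

        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(topo):
            node_grad = grads.pop(id(node), None)
            if node_grad is None or node._backward is None:
                if node_grad is not None and node._backward is None:
                    node.grad = node_grad if node.grad is None else node.grad + node_grad
                continue
            parent_grads = node._backward(node_grad)
            for parent, pgrad in zip(node._parents, parent_grads):
                if not parent.requires_grad or pgrad is None:
                    continue
                if parent._backward is None:
                    parent.grad = pgrad if parent.grad is None else parent.grad + pgrad
                else:
                    if id(parent) in grads:
                        grads[id(parent)] = grads[id(parent)] + pgrad
                    else:
                        grads[id(parent)] = pgrad


# -- structured ops -----------------------------------------------------------


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh = (h + 2 * pad - kh) // stride + 1
    ow = (w + 2 * pad - kw) // stride + 1
    sn, sc, sh, sw = x.strides
    cols = np.lib.stride_tricks.as_strided(
        x,
        shape=(n, c, kh, kw, oh, ow),
        strides=(sn, sc, sh, sw, sh * stride, sw * stride),
    )
    return np.ascontiguousarray(cols).reshape(n, c * kh * kw, oh * ow), oh, ow


def _col2im(cols: np.ndarray, x_shape, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    oh = (hp - kh) // stride + 1
    ow = (wp - kw) // stride + 1
    cols = cols.reshape(n, c, kh, kw, oh, ow)
    x = np.zeros((n, c, hp, wp), dtype=cols.dtype)
    for i in range(kh):
        for j in range(kw):
            x[:, :, i : i + oh * stride : stride, j : j + ow * stride : stride] += cols[
                :, :, i, j
            ]
    if pad:
        x = x[:, :, pad : hp - pad, pad : wp - pad]
    return x


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None, stride: int = 1, pad: int = 0):
    """2D convolution (cross-correlation) lowered to a single BLAS matmul.

    ``x``: (N, Cin, H, W); ``weight``: (Cout, Cin, kh, kw); ``bias``: (Cout,).
    """
    cout, cin, kh, kw = weight.shape
    n = x.shape[0]
    cols, oh, ow = _im2col(x.data, kh, kw, stride, pad)
    w2 = weight.data.reshape(cout, -1)
    out_data = np.einsum("of,nfp->nop", w2, cols, optimize=True)
    out_data = out_data.reshape(n, cout, oh, ow)
    if bias is not None:
        out_data = out_data + bias.data.reshape(1, cout, 1, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(grad):
        grad2 = grad.reshape(n, cout, oh * ow)
        dw = np.einsum("nop,nfp->of", grad2, cols, optimize=True).reshape(weight.shape)
        dcols = np.einsum("of,nop->nfp", w2, grad2, optimize=True)
        dx = _col2im(dcols, x.data.shape, kh, kw, stride, pad)
        if bias is None:
            return dx, dw
        return dx, dw, grad.sum(axis=(0, 2, 3))

    return Tensor._from_op(out_data, parents, backward)


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbor 2x spatial upsampling of an (N, C, H, W) tensor."""
    out_data = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def backward(grad):
        n, c, h2, w2 = grad.shape
        return (grad.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5)),)

    return Tensor._from_op(out_data, (x,), backward)


def concat(tensors: list[Tensor], axis: int) -> Tensor:
    """Concatenate tensors along an axis."""
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(grad):
        return tuple(np.split(grad, splits, axis=axis))

    return Tensor._from_op(out_data, tuple(tensors), backward)
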