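"""Minimal reverse-mode automatic differentiation on numpy arrays.

This is the numerical backend for the methylation classifier: a small
define-by-run tape with exactly the operations the network needs
(broadcast arithmetic, matmul, 1-D convolution building blocks, reductions,
sigmoid/relu/softplus). Gradients are accumulated by topological-order
backpropagation and are verified against central finite differences in the
test suite.

Design constraints:
  * float64 throughout — bit-reproducible runs on one platform matter more
    than speed at package-test scale;
  * no in-place mutation of ``data`` after a node is created;
  * broadcasting in forward ops is undone in backward by summing the
    gradient over broadcast axes (``_unbroadcast``).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "conv1d_same"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum away leading axes that were added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were 1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the autodiff graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- graph plumbing ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _make(self, data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this node (default seed: ones)."""
        if grad is None:
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
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(np.asarray(grad), self.data.shape)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad = self.grad + grad

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic -------------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._wrap(other)

        def backward(g):
            if self.requires_grad:
                self._accum(g)
            if other.requires_grad:
                other._accum(g)

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)

        def backward(g):
            if self.requires_grad:
                self._accum(g * other.data)
            if other.requires_grad:
                other._accum(g * self.data)

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)

        def backward(g):
            if self.requires_grad:
                self._accum(g / other.data)
            if other.requires_grad:
                other._accum(-g * self.data / (other.data**2))

        return self._make(self.data / other.data, (self, other), backward)

    def matmul(self, other: "Tensor") -> "Tensor":
        """Matrix product; supports batched left operand against a 2-D right."""
        other = self._wrap(other)

        def backward(g):
            if self.requires_grad:
                self._accum(g @ np.swapaxes(other.data, -1, -2))
            if other.requires_grad:
                go = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(go, other.data.shape))

        return self._make(self.data @ other.data, (self, other), backward)

    __matmul__ = matmul

    # -- nonlinearities ---------------------------------------------------
    def relu(self):
        mask = self.data > 0

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return self._make(self.data * mask, (self,), backward)

    def sigmoid(self):
        out_data = np.empty_like(self.data)
        pos = self.data >= 0
        out_data[pos] = 1.0 / (1.0 + np.exp(-self.data[pos]))
        ez = np.exp(self.data[~pos])
        out_data[~pos] = ez / (1.0 + ez)

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), backward)

    def softplus(self):
        # stable: softplus(x) = max(x, 0) + log1p(exp(-|x|))
        out_data = np.maximum(self.data, 0.0) + np.log1p(np.exp(-np.abs(self.data)))
        sig = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))

        def backward(g):
            if self.requires_grad:
                self._accum(g * sig)

        return self._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), backward)

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape))

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            n = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        out_data = self.data.max(axis=axis, keepdims=True)
        mask = self.data == out_data
        # split ties evenly so the gradient check passes at tied maxima
        mask = mask / mask.sum(axis=axis, keepdims=True)

        def backward(g):
            if self.requires_grad:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(gg * mask)

        data = out_data if keepdims else np.squeeze(out_data, axis=axis)
        return self._make(data, (self,), backward)

    # -- shape ops --------------------------------------------------------
    def reshape(self, *shape):
        orig = self.data.shape

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(orig))

        return self._make(self.data.reshape(*shape), (self,), backward)

    def transpose(self, *axes):
        inv = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accum(g.transpose(*inv))

        return self._make(self.data.transpose(*axes), (self,), backward)

    def pad_last(self, before: int, after: int):
        """Zero-pad the last axis (for 'same' convolutions)."""
        width = [(0, 0)] * (self.data.ndim - 1) + [(before, after)]

        def backward(g):
            if self.requires_grad:
                sl = [slice(None)] * (g.ndim - 1) + [
                    slice(before, g.shape[-1] - after if after else None)
                ]
                self._accum(g[tuple(sl)])

        return self._make(np.pad(self.data, width), (self,), backward)

    def slice_last(self, start: int, length: int):
        """Take ``[..., start:start+length]`` along the last axis."""

        def backward(g):
            if self.requires_grad:
                out = np.zeros(self.data.shape, dtype=np.float64)
                sl = [slice(None)] * (self.data.ndim - 1) + [slice(start, start + length)]
                out[tuple(sl)] = g
                self._accum(out)

        sl = [slice(None)] * (self.data.ndim - 1) + [slice(start, start + length)]
        return self._make(self.data[tuple(sl)], (self,), backward)

    def append_one(self):
        """Append a constant 1 along the last axis (fusion augmentation)."""
        ones_shape = self.data.shape[:-1] + (1,)
        data = np.concatenate([self.data, np.ones(ones_shape)], axis=-1)

        def backward(g):
            if self.requires_grad:
                self._accum(g[..., :-1])

        return self._make(data, (self,), backward)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def conv1d_same(x: Tensor, W: Tensor, b: Tensor) -> Tensor:
    """'same' 1-D convolution as one fused graph node.

    ``x``: (B, Cin, L); ``W``: (Cin, Cout, k); ``b``: (Cout,).
    Forward uses an im2col view + einsum; backward scatters the gradient
    back through the padding. Fused into a single node because the
    slice-per-tap formulation dominated the training profile.
    """
    B, Cin, L = x.data.shape
    k = W.data.shape[2]
    pad_left = k // 2
    pad_right = k - 1 - pad_left
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad_left, pad_right)))
    cols = np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)  # B,Cin,L,k
    out_data = np.einsum("bclk,cok->bol", cols, W.data, optimize=True) \
        + b.data[None, :, None]

    def backward(g):
        if W.requires_grad:
            W._accum(np.einsum("bclk,bol->cok", cols, g, optimize=True))
        if b.requires_grad:
            b._accum(g.sum(axis=(0, 2)))
        if x.requires_grad:
            dxp = np.zeros_like(xp)
            for j in range(k):
                dxp[:, :, j : j + L] += np.einsum(
                    "bol,co->bcl", g, W.data[:, :, j], optimize=True
                )
            end = xp.shape[2] - pad_right if pad_right else None
            x._accum(dxp[:, :, pad_left:end])

    out = Tensor(out_data)
    if x.requires_grad or W.requires_grad or b.requires_grad:
        out.requires_grad = True
        out._parents = (x, W, b)
        out._backward = backward
    return out


class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)
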