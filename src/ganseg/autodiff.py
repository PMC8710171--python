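"""Minimal reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it on a tape; :meth:`Tensor.backward` walks the tape in reverse topological
order and accumulates gradients into every tensor created with
``requires_grad=True``.  Only the primitives needed by the segmentation
networks are provided (elementwise arithmetic, matmul, reductions, shape
ops, the usual activations); convolution, pooling, upsampling and softmax
live in :mod:`ganseg.nnops`.

Gradients follow numpy broadcasting: the backward pass of a broadcast op
sums the upstream gradient over the broadcast axes so that ``t.grad`` always
has ``t.data``'s shape.  Correctness of every primitive is enforced by
central-difference checks in the test suite.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "as_tensor", "concat", "no_grad"]

_GRAD_ENABLED = [True]


class no_grad:
    """Context manager disabling tape construction (inference mode)."""

    def __enter__(self):
        self._prev = _GRAD_ENABLED[0]
        _GRAD_ENABLED[0] = False
        return self

    def __exit__(self, *exc):
        _GRAD_ENABLED[0] = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    # leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # axes of size 1 that were stretched
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An ndarray with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents",
                 "_accumulate_into")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED[0] and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        """A view of the same data cut off from the tape (stop-gradient)."""
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    # -- backward engine ------------------------------------------------------

    def backward(self, grad: np.ndarray | None = None) -> None:
        if not self.requires_grad:
            raise ValueError("backward() on a tensor that does not require grad")
        if grad is None:
            if self.data.size != 1:
                raise ValueError("grad must be supplied for non-scalar output")
            grad = np.ones_like(self.data)
        grad = np.asarray(grad, dtype=self.data.dtype)

        # reverse topological order over the tape
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))

        grads: dict[int, np.ndarray] = {id(self): grad}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is not None:
                node._accumulate_into = grads  # type: ignore[attr-defined]
                node._backward(g)
                del node._accumulate_into  # type: ignore[attr-defined]
            else:  # leaf
                node.grad = g if node.grad is None else node.grad + g
        # flush leaves that appeared only as parents (handled in _send)

    def _send(self, parent: "Tensor", g: np.ndarray) -> None:
        """Route gradient ``g`` to ``parent`` during a backward sweep."""
        if not parent.requires_grad:
            return
        if parent._backward is None:
            parent.grad = g if parent.grad is None else parent.grad + g
        else:
            grads = self._accumulate_into  # type: ignore[attr-defined]
            key = id(parent)
            if key in grads:
                grads[key] = grads[key] + g
            else:
                grads[key] = g

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other, self.dtype)
        a, b = self, other
        data = a.data + b.data

        def backward(g, out_ref=[None]):
            out = out_ref[0]
            out._send(a, _unbroadcast(g, a.shape))
            out._send(b, _unbroadcast(g, b.shape))

        out = Tensor._make(data, (a, b), lambda g: None)
        return _bind(out, backward)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def backward(g, out_ref=[None]):
            out_ref[0]._send(a, -g)

        return _bind(Tensor._make(-a.data, (a,), lambda g: None), backward)

    def __sub__(self, other):
        return self + (-as_tensor(other, self.dtype))

    def __rsub__(self, other):
        return as_tensor(other, self.dtype) + (-self)

    def __mul__(self, other):
        other = as_tensor(other, self.dtype)
        a, b = self, other

        def backward(g, out_ref=[None]):
            out = out_ref[0]
            out._send(a, _unbroadcast(g * b.data, a.shape))
            out._send(b, _unbroadcast(g * a.data, b.shape))

        return _bind(Tensor._make(a.data * b.data, (a, b), lambda g: None), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other, self.dtype)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return as_tensor(other, self.dtype) * self ** -1.0

    def __pow__(self, exponent: float):
        a = self
        p = float(exponent)
        data = a.data ** p

        def backward(g, out_ref=[None]):
            out_ref[0]._send(a, g * p * a.data ** (p - 1.0))

        return _bind(Tensor._make(data, (a,), lambda g: None), backward)

    def __matmul__(self, other):
        other = as_tensor(other, self.dtype)
        a, b = self, other
        data = a.data @ b.data

        def backward(g, out_ref=[None]):
            out = out_ref[0]
            if b.ndim >= 2:
                ga = g @ np.swapaxes(b.data, -1, -2)
            else:  # matrix @ vector
                ga = g[..., None] @ b.data[None, :]
            if a.ndim >= 2:
                gb = np.swapaxes(a.data, -1, -2) @ g
            else:
                gb = a.data[:, None] @ g[None, ...]
            out._send(a, _unbroadcast(ga, a.shape))
            out._send(b, _unbroadcast(gb, b.shape))

        return _bind(Tensor._make(data, (a, b), lambda g: None), backward)

    # -- activations / elementwise -------------------------------------------

    def relu(self):
        a = self
        mask = a.data > 0

        def backward(g, out_ref=[None]):
            out_ref[0]._send(a, g * mask)

        return _bind(Tensor._make(a.data * mask, (a,), lambda g: None), backward)

    def exp(self):
        a = self
        data = np.exp(a.data)

        def backward(g, out_ref=[None]):
            out_ref[0]._send(a, g * data)

        return _bind(Tensor._make(data, (a,), lambda g: None), backward)

    def log(self):
        a = self

        def backward(g, out_ref=[None]):
            out_ref[0]._send(a, g / a.data)

        return _bind(Tensor._make(np.log(a.data), (a,), lambda g: None), backward)

    def sigmoid(self):
        a = self
        data = 1.0 / (1.0 + np.exp(-a.data))

        def backward(g, out_ref=[None]):
            out_ref[0]._send(a, g * data * (1.0 - data))

        return _bind(Tensor._make(data, (a,), lambda g: None), backward)

    def clip(self, lo: float, hi: float):
        """Clamp values to [lo, hi]; gradient passes only inside the range."""
        a = self
        data = np.clip(a.data, lo, hi)
        mask = (a.data >= lo) & (a.data <= hi)

        def backward(g, out_ref=[None]):
            out_ref[0]._send(a, g * mask)

        return _bind(Tensor._make(data, (a,), lambda g: None), backward)

    # -- reductions & shape ops ----------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        a = self
        data = a.data.sum(axis=axis, keepdims=keepdims)

        def backward(g, out_ref=[None]):
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            out_ref[0]._send(a, np.broadcast_to(gg, a.shape).copy())

        return _bind(Tensor._make(data, (a,), lambda g: None), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[ax] for ax in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        old = a.shape

        def backward(g, out_ref=[None]):
            out_ref[0]._send(a, g.reshape(old))

        return _bind(Tensor._make(a.data.reshape(shape), (a,), lambda g: None), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        a = self
        inv = tuple(np.argsort(axes))

        def backward(g, out_ref=[None]):
            out_ref[0]._send(a, g.transpose(inv))

        return _bind(Tensor._make(a.data.transpose(axes), (a,), lambda g: None), backward)

    @property
    def T(self):
        return self.transpose(*reversed(range(self.ndim)))

    def __getitem__(self, idx):
        a = self

        def backward(g, out_ref=[None]):
            full = np.zeros(a.shape, dtype=g.dtype)
            full[idx] = g
            out_ref[0]._send(a, full)

        return _bind(Tensor._make(a.data[idx], (a,), lambda g: None), backward)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def _bind(out: Tensor, backward_fn) -> Tensor:
    """Attach ``backward_fn`` (written with an out_ref cell) to ``out``."""
    if out.requires_grad:
        cell = backward_fn.__defaults__[0]
        cell[0] = out
        out._backward = backward_fn
    return out


def as_tensor(x, dtype=None) -> Tensor:
    if isinstance(x, Tensor):
        return x
    arr = np.asarray(x)
    if dtype is not None and not np.issubdtype(arr.dtype, np.floating):
        arr = arr.astype(dtype)
    return Tensor(arr)


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = [as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def backward(g, out_ref=[None]):
        out = out_ref[0]
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            out._send(t, g[tuple(sl)])

    return _bind(Tensor._make(data, ts, lambda g: None), backward)
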