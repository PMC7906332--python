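"""Minimal reverse-mode automatic differentiation on numpy arrays.

This module exists because the adversarial loss of the model needs
second-order gradients: the gradient penalty of the Wasserstein critic is a
function of ``grad(D, y)`` and must itself be differentiated with respect to
the critic parameters.  Every vector-Jacobian product below is therefore
written in terms of the same primitive operations, so a backward pass run
with ``create_graph=True`` yields a differentiable graph.

Only the handful of primitives the networks need are provided; this is not a
general tensor library.  Activations with piecewise-linear kinks
(LeakyReLU, clip) treat their masks as constants, which matches the
almost-everywhere second derivative.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "grad",
    "leaky_relu",
    "matmul",
    "no_grad",
    "spmm",
]

# Global switch: when False, operations do not record the graph.  Used to run
# first-order backward passes without building second-order structure.
_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph recording."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


class Tensor:
    """A numpy array plus the tape entry that produced it."""

    __slots__ = ("data", "requires_grad", "grad", "_parents", "_vjp")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents: tuple = ()
        self._vjp = None

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def item(self) -> float:
        return float(self.data)

    # -- operator sugar -------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return mul(self, power(other, -1.0))
        return mul(self, 1.0 / other)

    def __neg__(self):
        return mul(self, -1.0)

    def __pow__(self, p):
        return power(self, p)

    def __matmul__(self, other):
        return matmul(self, other)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    @property
    def T(self):
        return transpose(self)

    def backward(self, grad_output=None):
        """Accumulate ``.grad`` (numpy arrays) on every reachable leaf."""
        grads = grad(self, None, grad_output=grad_output, create_graph=False)
        for t, g in grads.items():
            t.grad = g.data if t.grad is None else t.grad + g.data


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def _make(data, parents, vjp, requires: bool) -> Tensor:
    out = Tensor(data, requires_grad=requires and _GRAD_ENABLED)
    if out.requires_grad:
        out._parents = parents
        out._vjp = vjp
    return out


def _sum_to_shape(g: Tensor, shape) -> Tensor:
    """Reverse numpy broadcasting: reduce ``g`` down to ``shape``."""
    if g.shape == tuple(shape):
        return g
    # sum leading broadcast axes
    while g.ndim > len(shape):
        g = tsum(g, axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = tsum(g, axis=ax, keepdims=True)
    return reshape(g, tuple(shape))


# -- primitives ---------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    req = a.requires_grad or b.requires_grad
    return _make(
        a.data + b.data,
        (a, b),
        lambda g: (_sum_to_shape(g, a.shape), _sum_to_shape(g, b.shape)),
        req,
    )


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    req = a.requires_grad or b.requires_grad
    return _make(
        a.data * b.data,
        (a, b),
        lambda g: (_sum_to_shape(mul(g, b), a.shape), _sum_to_shape(mul(g, a), b.shape)),
        req,
    )


def power(a, p: float) -> Tensor:
    a = as_tensor(a)
    return _make(
        a.data ** p,
        (a,),
        lambda g: (mul(g, mul(power(a, p - 1.0), p)),),
        a.requires_grad,
    )


def exp(a) -> Tensor:
    a = as_tensor(a)
    out = _make(np.exp(a.data), (a,), None, a.requires_grad)
    if out.requires_grad:
        out._vjp = lambda g: (mul(g, out),)
    return out


def log(a) -> Tensor:
    a = as_tensor(a)
    return _make(np.log(a.data), (a,), lambda g: (mul(g, power(a, -1.0)),), a.requires_grad)


def sqrt(a) -> Tensor:
    a = as_tensor(a)
    out = _make(np.sqrt(a.data), (a,), None, a.requires_grad)
    if out.requires_grad:
        out._vjp = lambda g: (mul(g, mul(power(out, -1.0), 0.5)),)
    return out


def tanh(a) -> Tensor:
    a = as_tensor(a)
    out = _make(np.tanh(a.data), (a,), None, a.requires_grad)
    if out.requires_grad:
        out._vjp = lambda g: (mul(g, add(1.0, mul(mul(out, out), -1.0))),)
    return out


def leaky_relu(a, slope: float = 0.2) -> Tensor:
    a = as_tensor(a)
    mask = np.where(a.data > 0, 1.0, slope)  # constant a.e.
    return _make(a.data * mask, (a,), lambda g: (mul(g, Tensor(mask)),), a.requires_grad)


def clip(a, lo: float, hi: float) -> Tensor:
    a = as_tensor(a)
    mask = ((a.data >= lo) & (a.data <= hi)).astype(a.data.dtype)
    return _make(np.clip(a.data, lo, hi), (a,), lambda g: (mul(g, Tensor(mask)),), a.requires_grad)


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    req = a.requires_grad or b.requires_grad
    return _make(
        a.data @ b.data,
        (a, b),
        lambda g: (matmul(g, transpose(b)), matmul(transpose(a), g)),
        req,
    )


def transpose(a) -> Tensor:
    a = as_tensor(a)
    return _make(a.data.T, (a,), lambda g: (transpose(g),), a.requires_grad)


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    old = a.shape
    return _make(a.data.reshape(shape), (a,), lambda g: (reshape(g, old),), a.requires_grad)


def tsum(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    old = a.shape

    def vjp(g):
        gd = g
        if axis is not None and not keepdims:
            gd = reshape(gd, _keepdims_shape(old, axis))
        return (mul(Tensor(np.ones(old)), gd),)

    return _make(a.data.sum(axis=axis, keepdims=keepdims), (a,), vjp, a.requires_grad)


def _keepdims_shape(shape, axis):
    axes = (axis,) if isinstance(axis, int) else tuple(axis)
    axes = tuple(ax % len(shape) for ax in axes)
    return tuple(1 if i in axes else n for i, n in enumerate(shape))


def tmean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    n = a.data.size if axis is None else np.prod([a.shape[ax] for ax in np.atleast_1d(axis)])
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / float(n))


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    req = any(t.requires_grad for t in tensors)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def vjp(g):
        pieces = np.split(np.arange(int(np.sum(sizes))), splits)
        return tuple(take(g, idx, axis=axis) for idx in pieces)

    return _make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), vjp, req)


def take(a, indices, axis: int = -1) -> Tensor:
    a = as_tensor(a)
    indices = np.asarray(indices)
    old = a.shape

    def vjp(g):
        return (scatter_take(g, indices, axis, old),)

    return _make(np.take(a.data, indices, axis=axis), (a,), vjp, a.requires_grad)


def scatter_take(g, indices, axis, out_shape) -> Tensor:
    """Adjoint of :func:`take`: place slices of ``g`` back into zeros."""
    g = as_tensor(g)

    def vjp(gg):
        return (take(gg, indices, axis=axis),)

    data = np.zeros(out_shape, dtype=g.data.dtype)
    sl = [slice(None)] * len(out_shape)
    ax = axis % len(out_shape)
    np.add.at(data, tuple(sl[:ax] + [indices] + sl[ax + 1:]), g.data)
    return _make(data, (g,), vjp, g.requires_grad)


def spmm(S, a) -> Tensor:
    """Sparse (scipy) constant matrix times dense Tensor."""
    a = as_tensor(a)
    return _make(S @ a.data, (a,), lambda g: (spmm(S.T.tocsr(), g),), a.requires_grad)


# -- gradient driver ----------------------------------------------------------

def _topo(root: Tensor):
    order, seen, stack = [], set(), [(root, False)]
    while stack:
        node, done = stack.pop()
        if done:
            order.append(node)
            continue
        if id(node) in seen or not node.requires_grad:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            stack.append((p, False))
    return order


def grad(output: Tensor, inputs, grad_output=None, create_graph: bool = False):
    """Gradients of ``output`` w.r.t. ``inputs``.

    Returns a list aligned with ``inputs``, or — when ``inputs`` is None — a
    dict mapping every reachable leaf tensor to its gradient.  With
    ``create_graph=True`` the returned gradients are differentiable tensors.
    """
    if not output.requires_grad:
        raise ValueError("output does not require grad")
    if grad_output is None:
        grad_output = Tensor(np.ones_like(output.data))
    grads: dict[int, Tensor] = {id(output): as_tensor(grad_output)}
    holders: dict[int, Tensor] = {id(output): output}

    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = create_graph
    try:
        for node in reversed(_topo(output)):
            g = grads.pop(id(node), None)
            if g is None or node._vjp is None:
                if g is not None:
                    holders[id(node)] = node
                    grads[id(node)] = g
                continue
            for parent, pg in zip(node._parents, node._vjp(g)):
                if not parent.requires_grad:
                    continue
                key = id(parent)
                holders[key] = parent
                grads[key] = pg if key not in grads else add(grads[key], pg)
    finally:
        _GRAD_ENABLED = prev

    if inputs is None:
        return {holders[k]: v for k, v in grads.items() if holders[k]._vjp is None}
    out = []
    for t in inputs:
        g = grads.get(id(t))
        if g is None:
            g = Tensor(np.zeros_like(t.data))
        out.append(g)
    return out
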