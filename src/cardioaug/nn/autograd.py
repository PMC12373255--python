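"""Compact reverse-mode automatic differentiation on numpy arrays.

The engine records a dynamic computation graph of :class:`Tensor` nodes.
Every op's vector-Jacobian product is itself expressed in Tensor ops, so
``grad(..., create_graph=True)`` yields gradients that are again graph
nodes — i.e. higher-order derivatives work.  That is exactly what the
WGAN-GP gradient penalty needs: the penalty is a function of the critic's
input-gradient, and its parameter gradient requires differentiating
through the first backward pass.

Only the ops the networks in this package use are provided; everything is
float64 for cross-platform determinism.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "grad", "no_grad", "as_tensor", "concat"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph recording (eval-mode forward passes)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def _unbroadcast(g: "Tensor", shape: tuple) -> "Tensor":
    """Sum ``g`` down to ``shape`` (reverse of numpy broadcasting)."""
    if g.shape == shape:
        return g
    # sum leading extra axes
    while g.data.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g.reshape(shape)


class Tensor:
    __slots__ = ("data", "requires_grad", "grad", "_parents", "_vjp")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: Tensor | None = None
        self._parents: tuple = ()
        self._vjp = None  # callable(upstream: Tensor) -> tuple[Tensor|None, ...]

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self):
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"

    # -- graph plumbing -------------------------------------------------------
    @staticmethod
    def _make(data, parents, vjp):
        track = _GRAD_ENABLED and any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=track)
        if track:
            out._parents = tuple(parents)
            out._vjp = vjp
        return out

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor._make(self.data + other.data, (self, other),
                           lambda g: (_unbroadcast(g, self.shape),
                                      _unbroadcast(g, other.shape)))
        return out

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        return Tensor._make(self.data * other.data, (self, other),
                            lambda g: (_unbroadcast(g * other, self.shape),
                                       _unbroadcast(g * self, other.shape)))

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return as_tensor(other) * self ** -1.0

    def __pow__(self, p: float):
        p = float(p)
        return Tensor._make(self.data ** p, (self,),
                            lambda g: (g * (p * self ** (p - 1.0)),))

    def __matmul__(self, other):
        other = as_tensor(other)
        if self.data.ndim < 2 or other.data.ndim < 2:
            raise ValueError("matmul requires >= 2-D operands")

        def vjp(g):
            ga = _unbroadcast(g @ other.swap_last(), self.shape)
            gb = _unbroadcast(self.swap_last() @ g, other.shape)
            return (ga, gb)

        return Tensor._make(self.data @ other.data, (self, other), vjp)

    def swap_last(self) -> "Tensor":
        """Transpose the last two axes (matmul adjoint helper)."""
        axes = tuple(range(self.data.ndim - 2)) + \
            (self.data.ndim - 1, self.data.ndim - 2)
        return self.transpose(*axes)

    @property
    def T(self) -> "Tensor":
        axes = tuple(reversed(range(self.data.ndim)))
        return self.transpose(*axes)

    def transpose(self, *axes) -> "Tensor":
        if not axes:
            axes = tuple(reversed(range(self.data.ndim)))
        inv = tuple(np.argsort(axes))
        return Tensor._make(self.data.transpose(axes), (self,),
                            lambda g: (g.transpose(*inv),))

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        return Tensor._make(self.data.reshape(shape), (self,),
                            lambda g: (g.reshape(old),))

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self) -> "Tensor":
        out = Tensor._make(np.exp(self.data), (self,), None)
        if out._parents:
            out._vjp = lambda g: (g * out,)
        return out

    def log(self) -> "Tensor":
        return Tensor._make(np.log(self.data), (self,),
                            lambda g: (g / self,))

    def sqrt(self) -> "Tensor":
        return self ** 0.5

    def tanh(self) -> "Tensor":
        out = Tensor._make(np.tanh(self.data), (self,), None)
        if out._parents:
            out._vjp = lambda g: (g * (1.0 - out * out),)
        return out

    def relu(self) -> "Tensor":
        mask = (self.data > 0).astype(np.float64)
        return Tensor._make(self.data * mask, (self,),
                            lambda g: (g * Tensor(mask),))

    def leaky_relu(self, slope: float = 0.2) -> "Tensor":
        fac = np.where(self.data > 0, 1.0, slope)
        return Tensor._make(self.data * fac, (self,),
                            lambda g: (g * Tensor(fac),))

    def abs(self) -> "Tensor":
        sign = np.sign(self.data)
        return Tensor._make(np.abs(self.data), (self,),
                            lambda g: (g * Tensor(sign),))

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor._make(s, (self,), None)
        if out._parents:
            out._vjp = lambda g: (g * out * (1.0 - out),)
        return out

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        old = self.shape

        def vjp(g):
            gd = g
            if axis is not None and not keepdims:
                axes = (axis,) if isinstance(axis, int) else tuple(axis)
                shp = list(g.shape)
                for ax in sorted(a % len(old) for a in axes):
                    shp.insert(ax, 1)
                gd = g.reshape(tuple(shp))
            return (gd.broadcast_to(old),)

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims),
                            (self,), vjp)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def broadcast_to(self, shape) -> "Tensor":
        old = self.shape
        return Tensor._make(np.broadcast_to(self.data, shape), (self,),
                            lambda g: (_unbroadcast(g, old),))

    def max_detached(self, axis=None, keepdims=False) -> "Tensor":
        """Max treated as a constant (used for numerically stable softmax)."""
        return Tensor(self.data.max(axis=axis, keepdims=keepdims))

    # -- indexing -------------------------------------------------------------
    def take(self, indices, axis: int = 0) -> "Tensor":
        """Gather rows/slices; VJP is scatter-add (itself differentiable)."""
        indices = np.asarray(indices, dtype=np.intp)
        shape = self.shape

        def vjp(g):
            return (g.scatter_add(indices, shape, axis),)

        return Tensor._make(np.take(self.data, indices, axis=axis),
                            (self,), vjp)

    def scatter_add(self, indices, out_shape, axis: int = 0) -> "Tensor":
        indices = np.asarray(indices, dtype=np.intp)
        buf = np.zeros(out_shape, dtype=np.float64)
        np.add.at(np.moveaxis(buf, axis, 0), indices,
                  np.moveaxis(self.data, axis, 0))

        def vjp(g):
            return (g.take(indices, axis=axis),)

        return Tensor._make(buf, (self,), vjp)

    def __getitem__(self, key):
        shape = self.shape

        def vjp(g):
            return (_SetSlice.apply(g, key, shape),)

        return Tensor._make(self.data[key], (self,), vjp)


class _SetSlice:
    """Zero tensor of `shape` with `g` placed at `key` (VJP of __getitem__)."""

    @staticmethod
    def apply(g: Tensor, key, shape) -> Tensor:
        buf = np.zeros(shape)
        buf[key] = g.data  # basic slicing: no duplicate indices

        def vjp(up):
            return (up[key],)

        return Tensor._make(buf, (g,), vjp)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offs = np.cumsum([0] + sizes)

    def vjp(g):
        outs = []
        for i, t in enumerate(tensors):
            key = [slice(None)] * g.data.ndim
            key[axis] = slice(int(offs[i]), int(offs[i + 1]))
            outs.append(g[tuple(key)])
        return tuple(outs)

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis),
                        tensors, vjp)


def _toposort(root: Tensor):
    order, seen, stack = [], set(), [(root, False)]
    while stack:
        node, done = stack.pop()
        if done:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            if id(p) not in seen:
                stack.append((p, False))
    return order  # children after parents


def grad(output: Tensor, inputs, create_graph: bool = False,
         allow_unused: bool = False):
    """Gradients of a scalar ``output`` w.r.t. ``inputs``.

    With ``create_graph=True`` the returned gradients are graph nodes and
    can be differentiated again (needed for the gradient penalty).
    """
    single = isinstance(inputs, Tensor)
    if single:
        inputs = [inputs]
    if output.size != 1:
        raise ValueError("grad() expects a scalar output")

    grads: dict[int, Tensor] = {id(output): Tensor(np.ones_like(output.data))}
    order = _toposort(output)

    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = create_graph
    try:
        for node in reversed(order):
            g = grads.pop(id(node), None)
            if g is None or node._vjp is None:
                if g is not None:
                    grads[id(node)] = g  # keep leaves
                continue
            parent_grads = node._vjp(g)
            for p, pg in zip(node._parents, parent_grads):
                if pg is None or not (p.requires_grad or p._parents):
                    continue
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg
    finally:
        _GRAD_ENABLED = prev

    out = []
    for inp in inputs:
        g = grads.get(id(inp))
        if g is None:
            if not allow_unused:
                raise RuntimeError("an input does not influence the output")
            g = Tensor(np.zeros_like(inp.data))
        out.append(g)
    return out[0] if single else out


def backward(loss: Tensor, params) -> None:
    """Populate ``p.grad`` (as plain Tensors) for each parameter."""
    gs = grad(loss, list(params), create_graph=False, allow_unused=True)
    for p, g in zip(params, gs):
        p.grad = g if p.grad is None else Tensor(p.grad.data + g.data)
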