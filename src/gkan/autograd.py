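"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small tape-based engine: every operation records its parents
and a vector-Jacobian product (VJP) written in terms of other :class:`Tensor`
operations.  Because the VJPs themselves build graph nodes when
``create_graph=True``, gradients of gradients are available — this is what the
Wasserstein-GAN gradient penalty needs (a parameter gradient of an
input-gradient norm).

Only the primitives required by the spline/KAN layer zoo are implemented:
elementwise arithmetic, matmul, reductions, reshaping, slicing, padding and a
1-D sliding-window unfold/fold pair for convolutions.  All data is float64.
"""

from __future__ import annotations

import contextlib
from typing import Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "tensor", "no_grad", "is_grad_enabled", "grad", "concat"]

_GRAD_ENABLED = [True]


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED[0]


@contextlib.contextmanager
def no_grad():
    """Context manager disabling graph construction."""
    prev = _GRAD_ENABLED[0]
    _GRAD_ENABLED[0] = False
    try:
        yield
    finally:
        _GRAD_ENABLED[0] = prev


@contextlib.contextmanager
def _enable_grad():
    prev = _GRAD_ENABLED[0]
    _GRAD_ENABLED[0] = True
    try:
        yield
    finally:
        _GRAD_ENABLED[0] = prev


def _as_array(x) -> np.ndarray:
    if isinstance(x, Tensor):
        raise TypeError("expected raw array, got Tensor")
    return np.asarray(x, dtype=np.float64)


class Tensor:
    """A numpy array with an optional autodiff tape entry."""

    __slots__ = ("data", "requires_grad", "grad", "_parents", "_vjp")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.requires_grad = bool(requires_grad)
        self.grad: Tensor | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._vjp = None

    # -- construction of graph nodes -------------------------------------
    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"], vjp) -> "Tensor":
        out = Tensor.__new__(Tensor)
        out.data = data
        out.grad = None
        if _GRAD_ENABLED[0] and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._vjp = vjp
        else:
            out.requires_grad = False
            out._parents = ()
            out._vjp = None
        return out

    # -- basic protocol ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __len__(self):
        return len(self.data)

    def __repr__(self):
        return f"Tensor({self.data!r}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    # -- elementwise arithmetic ------------------------------------------
    def __add__(self, other):
        other = _wrap(other)
        a, b = self, other
        data = a.data + b.data

        def vjp(g):
            return (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape))

        return Tensor._make(data, (a, b), vjp)

    __radd__ = __add__

    def __neg__(self):
        a = self
        return Tensor._make(-a.data, (a,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-_wrap(other))

    def __rsub__(self, other):
        return _wrap(other) + (-self)

    def __mul__(self, other):
        other = _wrap(other)
        a, b = self, other
        data = a.data * b.data

        def vjp(g):
            return (_unbroadcast(g * b, a.shape), _unbroadcast(g * a, b.shape))

        return Tensor._make(data, (a, b), vjp)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * _wrap(other) ** -1.0

    def __rtruediv__(self, other):
        return _wrap(other) * self ** -1.0

    def __pow__(self, p: float):
        if isinstance(p, Tensor):
            raise TypeError("only scalar exponents are supported")
        a = self
        p = float(p)
        data = a.data ** p

        def vjp(g):
            return (g * (p * a ** (p - 1.0)),)

        return Tensor._make(data, (a,), vjp)

    # -- transcendental ----------------------------------------------------
    # The transcendental VJPs multiply by a precomputed derivative array
    # (a constant w.r.t. the tape) instead of referencing the output node:
    # this keeps the graph cycle-free so large activations free promptly.
    # Second-order gradients therefore flow through the polynomial /
    # piecewise-linear op family (arithmetic, matmul, conv, relu, abs),
    # which is the family the Wasserstein critic is built from.
    def exp(self):
        a = self
        data = np.exp(a.data)
        return Tensor._make(data, (a,), lambda g: (g * Tensor(data),))

    def log(self):
        a = self
        return Tensor._make(np.log(a.data), (a,),
                            lambda g: (g * Tensor(1.0 / a.data),))

    def sqrt(self):
        return self ** 0.5

    def tanh(self):
        a = self
        data = np.tanh(a.data)
        return Tensor._make(data, (a,), lambda g: (g * Tensor(1.0 - data * data),))

    def sigmoid(self):
        a = self
        data = 1.0 / (1.0 + np.exp(-a.data))
        return Tensor._make(data, (a,), lambda g: (g * Tensor(data * (1.0 - data)),))

    def relu(self):
        a = self
        mask = (a.data > 0).astype(np.float64)
        return Tensor._make(a.data * mask, (a,), lambda g: (g * Tensor(mask),))

    def silu(self):
        """Sigmoid-weighted linear unit x * sigmoid(x)."""
        return self * self.sigmoid()

    def abs(self):
        a = self
        sign = np.sign(a.data)
        return Tensor._make(np.abs(a.data), (a,), lambda g: (g * Tensor(sign),))

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self
        data = a.data.sum(axis=axis, keepdims=keepdims)

        def vjp(g):
            gd = g
            if axis is not None and not keepdims:
                gd = gd.reshape(_keepdims_shape(a.shape, axis))
            return (gd.broadcast_to(a.shape),)

        return Tensor._make(data, (a,), vjp)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.size if axis is None else np.prod(
            [self.shape[ax] for ax in _normalize_axes(axis, self.ndim)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis=None, keepdims: bool = False):
        # Used for numerically stable softmax; treated as a constant shift.
        return Tensor(self.data.max(axis=axis, keepdims=keepdims))

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        orig = a.shape
        return Tensor._make(
            a.data.reshape(shape), (a,), lambda g: (g.reshape(orig),)
        )

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        if not axes:
            axes = tuple(reversed(range(self.ndim)))
        a = self
        inv = tuple(np.argsort(axes))
        return Tensor._make(
            a.data.transpose(axes), (a,), lambda g: (g.transpose(inv),)
        )

    @property
    def T(self):
        return self.transpose()

    def broadcast_to(self, shape):
        a = self
        if a.shape == tuple(shape):
            return a
        return Tensor._make(
            np.broadcast_to(a.data, shape).copy(),
            (a,),
            lambda g: (_unbroadcast(g, a.shape),),
        )

    def __getitem__(self, key):
        a = self
        data = a.data[key]
        shape = a.shape

        def vjp(g):
            return (_scatter(g, key, shape),)

        return Tensor._make(data, (a,), vjp)

    # -- linear algebra ----------------------------------------------------
    def __matmul__(self, other):
        other = _wrap(other)
        a, b = self, other
        if a.ndim != 2 or b.ndim != 2:
            raise ValueError("matmul supports 2-D operands only")
        data = a.data @ b.data

        def vjp(g):
            return (g @ b.T, a.T @ g)

        return Tensor._make(data, (a, b), vjp)

    # -- sequence ops ------------------------------------------------------
    def pad_last(self, before: int, after: int):
        """Zero-pad the last axis."""
        a = self
        if before == 0 and after == 0:
            return a
        width = [(0, 0)] * (a.ndim - 1) + [(before, after)]
        data = np.pad(a.data, width)
        L = a.shape[-1]

        def vjp(g):
            return (g[..., before:before + L],)

        return Tensor._make(data, (a,), vjp)

    def unfold1d(self, kernel_size: int, stride: int = 1):
        """(..., L) -> (..., L_out, kernel_size) sliding windows."""
        a = self
        L = a.shape[-1]
        if kernel_size > L:
            raise ValueError(f"kernel {kernel_size} larger than length {L}")
        win = np.lib.stride_tricks.sliding_window_view(a.data, kernel_size, axis=-1)
        data = np.ascontiguousarray(win[..., ::stride, :])

        def vjp(g):
            return (g.fold1d(L, stride),)

        return Tensor._make(data, (a,), vjp)

    def fold1d(self, out_length: int, stride: int = 1):
        """Adjoint of :meth:`unfold1d`: overlap-add windows back to length."""
        a = self
        k = a.shape[-1]
        l_out = a.shape[-2]
        lead = a.shape[:-2]
        data = np.zeros(lead + (out_length,), dtype=np.float64)
        for t in range(k):  # k is small (<= kernel size); vectorized over the rest
            data[..., t:t + l_out * stride:stride][..., :l_out] += a.data[..., :, t]

        def vjp(g):
            return (g.unfold1d(k, stride),)

        return Tensor._make(data, (a,), vjp)

    # -- autodiff ----------------------------------------------------------
    def conv1d(self, weight: "Tensor", stride: int = 1, padding: int = 0):
        """Cross-correlate (B, C, L) with (O, C, K) -> (B, O, L_out).

        The VJPs are expressed through :func:`_conv_input_grad` and
        :func:`_conv_weight_grad`, which are themselves primitives whose VJPs
        come back to ``conv1d`` — the three form a closed, twice-
        differentiable family (needed for gradient penalties).
        """
        return _conv1d(self, weight, stride, padding)

    # -- backward entry points ---------------------------------------------
    def backward(self, gradient=None, create_graph: bool = False):
        if gradient is None:
            if self.size != 1:
                raise ValueError("backward() on non-scalar needs an explicit gradient")
            gradient = Tensor(np.ones_like(self.data))
        elif not isinstance(gradient, Tensor):
            gradient = Tensor(gradient)
        grads = _backprop(self, gradient, create_graph)
        for t, g in grads.items():
            if t.requires_grad and t._vjp is None:
                t.grad = g if t.grad is None else t.grad + g


def grad(
    output: Tensor,
    inputs: Iterable[Tensor],
    create_graph: bool = False,
) -> list[Tensor]:
    """Gradients of a scalar ``output`` w.r.t. ``inputs``, without touching .grad."""
    inputs = list(inputs)
    if output.size != 1:
        raise ValueError("grad() expects a scalar output")
    grads = _backprop(output, Tensor(np.ones_like(output.data)), create_graph)
    out = []
    for t in inputs:
        g = grads.get(t)
        if g is None:
            g = Tensor(np.zeros_like(t.data))
        out.append(g)
    return out


def _backprop(root: Tensor, seed: Tensor, create_graph: bool) -> dict:
    topo: list[Tensor] = []
    seen: set[int] = set()
    stack = [(root, False)]
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
            if id(p) not in seen:
                stack.append((p, False))

    grads: dict[Tensor, Tensor] = {root: seed}
    ctx = _enable_grad() if create_graph else no_grad()
    with ctx:
        for node in reversed(topo):
            g = grads.get(node)
            if g is None or node._vjp is None:
                continue
            parent_grads = node._vjp(g)
            for p, pg in zip(node._parents, parent_grads):
                if pg is None or not p.requires_grad:
                    continue
                acc = grads.get(p)
                grads[p] = pg if acc is None else acc + pg
    # keys by identity for leaves
    return {k: v for k, v in grads.items()}


class _IdentityDict(dict):
    pass


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def tensor(data, requires_grad: bool = False) -> Tensor:
    return Tensor(data, requires_grad=requires_grad)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def vjp(g):
        outs = []
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            key = [slice(None)] * g.ndim
            key[axis] = slice(int(lo), int(hi))
            outs.append(g[tuple(key)])
        return tuple(outs)

    return Tensor._make(data, tensors, vjp)


# -- 1-D convolution primitive family ---------------------------------------
#
# F(x, w)  : correlation        (B,C,L) x (O,C,K) -> (B,O,Lo)
# G1(g, w) : input gradient     (B,O,Lo) x (O,C,K) -> (B,C,L)
# G2(x, g) : weight gradient    (B,C,L) x (B,O,Lo) -> (O,C,K)
# Their VJPs close over each other:  dF = (G1, G2), dG1 = (F, G2'), dG2 = (G1, F).
# All three loop over the (small) kernel axis and hand the rest to BLAS.


def _conv_fwd_np(x: np.ndarray, w: np.ndarray, stride: int, padding: int) -> np.ndarray:
    b, c, L = x.shape
    o, _, k = w.shape
    if padding:
        x = np.pad(x, ((0, 0), (0, 0), (padding, padding)))
    lp = x.shape[-1]
    lo = (lp - k) // stride + 1
    if lo < 1:
        raise ValueError("kernel larger than padded input")
    y = np.zeros((b, o, lo))
    end = (lo - 1) * stride + 1
    for t in range(k):
        y += np.matmul(w[:, :, t], x[:, :, t:t + end:stride])
    return y


def _conv_dx_np(g: np.ndarray, w: np.ndarray, stride: int, padding: int,
                in_length: int) -> np.ndarray:
    b, o, lo = g.shape
    _, c, k = w.shape
    lp = in_length + 2 * padding
    dxp = np.zeros((b, c, lp))
    end = (lo - 1) * stride + 1
    for t in range(k):
        dxp[:, :, t:t + end:stride] += np.matmul(w[:, :, t].T, g)
    return dxp[:, :, padding:padding + in_length]


def _conv_dw_np(x: np.ndarray, g: np.ndarray, stride: int, padding: int,
                kernel_size: int) -> np.ndarray:
    b, o, lo = g.shape
    if padding:
        x = np.pad(x, ((0, 0), (0, 0), (padding, padding)))
    c = x.shape[1]
    dw = np.empty((o, c, kernel_size))
    end = (lo - 1) * stride + 1
    for t in range(kernel_size):
        dw[:, :, t] = np.tensordot(g, x[:, :, t:t + end:stride],
                                   axes=([0, 2], [0, 2]))
    return dw


def _conv1d(x: Tensor, w: Tensor, stride: int, padding: int) -> Tensor:
    data = _conv_fwd_np(x.data, w.data, stride, padding)
    L = x.shape[-1]
    k = w.shape[-1]

    def vjp(g):
        return (_conv_input_grad(g, w, stride, padding, L),
                _conv_weight_grad(x, g, stride, padding, k))

    return Tensor._make(data, (x, w), vjp)


def _conv_input_grad(g: Tensor, w: Tensor, stride: int, padding: int,
                     in_length: int) -> Tensor:
    data = _conv_dx_np(g.data, w.data, stride, padding, in_length)
    k = w.shape[-1]

    def vjp(h):
        # <G1(g, w), h> = <g, F(h, w)> = <w, G2(h, g)>
        return (_conv1d(h, w, stride, padding),
                _conv_weight_grad(h, g, stride, padding, k))

    return Tensor._make(data, (g, w), vjp)


def _conv_weight_grad(x: Tensor, g: Tensor, stride: int, padding: int,
                      kernel_size: int) -> Tensor:
    data = _conv_dw_np(x.data, g.data, stride, padding, kernel_size)
    L = x.shape[-1]

    def vjp(u):
        # <G2(x, g), u> = <g, F(x, u)> = <x, G1(g, u)>
        return (_conv_input_grad(g, u, stride, padding, L),
                _conv1d(x, u, stride, padding))

    return Tensor._make(data, (x, g), vjp)


def _normalize_axes(axis, ndim) -> tuple:
    if axis is None:
        return tuple(range(ndim))
    if isinstance(axis, int):
        axis = (axis,)
    return tuple(ax % ndim for ax in axis)


def _keepdims_shape(shape, axis):
    axes = _normalize_axes(axis, len(shape))
    return tuple(1 if i in axes else s for i, s in enumerate(shape))


def _unbroadcast(g: Tensor, shape: tuple) -> Tensor:
    """Reduce a gradient back to the shape of a broadcast operand."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


def _scatter(g: Tensor, key, shape) -> Tensor:
    """Place gradient ``g`` into a zero tensor of ``shape`` at ``key``."""
    a = g
    data = np.zeros(shape, dtype=np.float64)
    parts = key if isinstance(key, tuple) else (key,)
    if any(isinstance(p, (np.ndarray, list)) for p in parts):
        np.add.at(data, key, a.data)  # integer-array keys may repeat positions
    else:
        data[key] += a.data

    def vjp(gg):
        return (gg[key],)

    return Tensor._make(data, (a,), vjp)
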