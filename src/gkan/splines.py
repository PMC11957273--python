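"""Uniform B-spline grids and basis evaluation.

Every edge function in a Kolmogorov-Arnold layer is a linear combination of
B-spline basis functions over a fixed uniform knot grid.  The grid has G
interior intervals on [lo, hi] and degree k, giving G + k basis functions;
k extra knots on each side replicate the interior spacing so that the basis
is complete up to the domain boundary.

Two evaluation paths are provided: a plain numpy one
(:func:`bspline_basis`) and an autodiff one (:func:`bspline_basis_tensor`)
used inside KAN layers, both the same iterative Cox-de Boor recursion.
Inputs outside [lo, hi] are evaluated by the same recursion (rows may sum to
less than one there) rather than clamped, preserving differentiability
during training; pass ``clamp=True`` to clip inputs into the domain first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autograd import Tensor

__all__ = ["SplineGrid", "build_grid", "bspline_basis", "bspline_basis_tensor"]


@dataclass(frozen=True)
class SplineGrid:
    """Knot vector and degree defining a univariate B-spline basis.

    Attributes
    ----------
    lo, hi : float
        Domain bounds; the G interior intervals tile [lo, hi].
    num_intervals : int
        Grid size G >= 1 — the capacity knob of every KAN edge function.
    degree : int
        Spline degree k >= 0 (k = 3 is the cubic default).
    knots : ndarray
        Ordered knot vector of length G + 2k + 1.
    """

    lo: float
    hi: float
    num_intervals: int
    degree: int
    knots: np.ndarray = field(repr=False)

    @property
    def basis_dim(self) -> int:
        """Number of basis functions, G + k."""
        return self.num_intervals + self.degree

    @property
    def spacing(self) -> float:
        return (self.hi - self.lo) / self.num_intervals

    def to_dict(self) -> dict:
        return {
            "lo": self.lo,
            "hi": self.hi,
            "num_intervals": self.num_intervals,
            "degree": self.degree,
        }

    @staticmethod
    def from_dict(d: dict) -> "SplineGrid":
        return build_grid(d["lo"], d["hi"], d["num_intervals"], d["degree"])


def build_grid(lo: float, hi: float, num_intervals: int, degree: int) -> SplineGrid:
    """Construct a uniform grid with ``degree`` extension knots per side."""
    lo, hi = float(lo), float(hi)
    if not (np.isfinite(lo) and np.isfinite(hi)):
        raise ValueError("grid bounds must be finite")
    if lo >= hi:
        raise ValueError(f"need lo < hi, got [{lo}, {hi}]")
    if num_intervals < 1:
        raise ValueError(f"num_intervals must be >= 1, got {num_intervals}")
    if degree < 0:
        raise ValueError(f"degree must be >= 0, got {degree}")
    h = (hi - lo) / num_intervals
    idx = np.arange(-degree, num_intervals + degree + 1, dtype=np.float64)
    knots = lo + h * idx
    return SplineGrid(lo=lo, hi=hi, num_intervals=num_intervals,
                      degree=degree, knots=knots)


def _degree_zero(x: np.ndarray, grid: SplineGrid) -> np.ndarray:
    """Interval indicators over all G + 2k spans; right endpoint closed at hi."""
    t = grid.knots
    n0 = len(t) - 1
    idx = np.searchsorted(t, x, side="right") - 1
    # x == hi falls out of the half-open interior interval; fold it back in
    at_hi = x == grid.hi
    idx = np.where(at_hi, grid.degree + grid.num_intervals - 1, idx)
    rows = np.arange(x.size)
    b0 = np.zeros((x.size, n0))
    valid = (idx >= 0) & (idx < n0)
    b0[rows[valid], idx[valid]] = 1.0
    return b0


def bspline_basis(x, grid: SplineGrid, clamp: bool = False) -> np.ndarray:
    """Evaluate all G + k basis functions at each x; rows are basis vectors.

    Uses the iterative (vectorized) Cox-de Boor recursion.  On [lo, hi] the
    rows form a partition of unity.
    """
    x = np.asarray(x, dtype=np.float64).reshape(-1)
    if not np.all(np.isfinite(x)):
        raise ValueError("spline inputs must be finite")
    if clamp:
        x = np.clip(x, grid.lo, grid.hi)
    t = grid.knots
    b = _degree_zero(x, grid)
    for d in range(1, grid.degree + 1):
        n_prev = b.shape[1]
        left_t = t[: n_prev - 1]
        denom1 = t[d: d + n_prev - 1] - left_t          # uniform: d * h
        denom2 = t[d + 1: d + n_prev] - t[1: n_prev]
        term1 = (x[:, None] - left_t) / denom1 * b[:, :-1]
        term2 = (t[d + 1: d + n_prev] - x[:, None]) / denom2 * b[:, 1:]
        b = term1 + term2
    return b


def _basis_to_degree(x: np.ndarray, grid: SplineGrid, degree: int) -> np.ndarray:
    """Cox-de Boor recursion up to ``degree`` over the grid's knot vector."""
    t = grid.knots
    b = _degree_zero(x, grid)
    for d in range(1, degree + 1):
        n_prev = b.shape[1]
        left_t = t[: n_prev - 1]
        denom1 = t[d: d + n_prev - 1] - left_t
        denom2 = t[d + 1: d + n_prev] - t[1: n_prev]
        term1 = (x[:, None] - left_t) / denom1 * b[:, :-1]
        term2 = (t[d + 1: d + n_prev] - x[:, None]) / denom2 * b[:, 1:]
        b = term1 + term2
    return b


def _basis_deriv_np(x: np.ndarray, grid: SplineGrid, deriv: int) -> np.ndarray:
    """r-th derivative of all degree-k basis functions at x.

    Uses the derivative recursion
    d/dx B_{m,k} = k (B_{m,k-1}/(t_{m+k}-t_m) - B_{m+1,k-1}/(t_{m+k+1}-t_{m+1})),
    applied ``deriv`` times; derivatives beyond the degree vanish.
    """
    return _basis_deriv_np_at_degree(x, grid, grid.degree, deriv)


def _basis_deriv_np_at_degree(x: np.ndarray, grid: SplineGrid, degree: int,
                              deriv: int) -> np.ndarray:
    if deriv == 0:
        return _basis_to_degree(x, grid, degree)
    if deriv > degree:
        return np.zeros((x.size, len(grid.knots) - 1 - degree))
    t = grid.knots
    low = _basis_deriv_np_at_degree(x, grid, degree - 1, deriv - 1)
    n = len(t) - 1 - degree
    den1 = t[degree: degree + n] - t[:n]
    den2 = t[degree + 1: degree + 1 + n] - t[1: 1 + n]
    return degree * (low[:, :n] / den1 - low[:, 1: n + 1] / den2)


def bspline_basis_tensor(x: Tensor, grid: SplineGrid, clamp: bool = False,
                         _deriv: int = 0) -> Tensor:
    """Autodiff counterpart of :func:`bspline_basis` for a flat input tensor.

    Implemented as one fused primitive: the forward pass runs the plain
    numpy recursion, and the VJP multiplies the upstream gradient by the
    analytic basis derivative — itself produced by this same function at the
    next derivative order, so higher-order gradients remain available
    without retaining the recursion's intermediates in memory.
    """
    if x.ndim != 1:
        raise ValueError("expected a flat tensor of evaluation points")
    if not np.all(np.isfinite(x.data)):
        raise ValueError("spline inputs must be finite")
    if clamp:
        xd = np.clip(x.data, grid.lo, grid.hi)
        inside = ((x.data >= grid.lo) & (x.data <= grid.hi)).astype(np.float64)
    else:
        xd = x.data
        inside = None
    data = _basis_deriv_np(xd, grid, _deriv)

    def vjp(g):
        db = bspline_basis_tensor(x, grid, clamp=clamp, _deriv=_deriv + 1)
        gx = (g * db).sum(axis=1)
        if inside is not None:
            gx = gx * Tensor(inside)
        return (gx,)

    return Tensor._make(data, (x,), vjp)
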