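"""Linear and convolutional Kolmogorov-Arnold layers.

A KAN layer carries one learnable univariate function per edge instead of a
scalar weight:

    phi(x) = w_base * sigma(x) + s * sum_m c_m B_m(x)

with sigma a fixed base activation (SiLU by default), B_m the B-spline basis
of a shared :class:`~gkan.splines.SplineGrid`, c_m learnable spline
coefficients and s an optional learnable scaler.  The efficient formulation
evaluates the basis once per input scalar and folds the edge sums into plain
matrix multiplications, so a linear KAN is a dense layer over the
basis-expanded input, and a 1-D KAN convolution is the same kernel applied to
unfolded sliding windows.

Parameter and FLOP accounting helpers live here too: grid size G enters the
parameter count linearly (slope n_in * n_out for a linear KAN), which is the
mechanism behind the parameter-vs-grid-size scaling curve of the ablation.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor
from .nn import ACTIVATIONS, Conv1d, Dense, Module, Parameter, rng_for
from .splines import SplineGrid, bspline_basis_tensor, build_grid

__all__ = [
    "LinearKAN", "ConvKAN", "linear_kan_forward", "conv_kan_forward",
    "kan_regularization", "count_parameters", "estimate_flops",
    "linear_kan_param_count", "conv_kan_param_count",
]


def _check_finite(x: np.ndarray, what: str):
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{what} contains non-finite values")


class LinearKAN(Module):
    """Dense-replacement KAN layer: one spline edge function per (out, in) pair.

    Parameters
    ----------
    n_in, n_out : int
        Input and output widths.
    grid : SplineGrid, optional
        Shared basis grid; defaults to G=5 cubic splines on [-1, 1].
    base_activation : str
        Name of the residual base activation sigma ('silu', 'relu',
        'identity', ...).
    use_scaler : bool
        Learn a per-edge multiplier on the spline branch (on by default;
        credited with stabilizing training of linear KANs).
    clamp_inputs : bool
        Clip inputs into the grid domain before basis evaluation.
    """

    def __init__(self, n_in: int, n_out: int, grid: SplineGrid | None = None,
                 base_activation: str = "silu", use_scaler: bool = True,
                 clamp_inputs: bool = False, seed: int = 0, name: str = "lkan"):
        super().__init__()
        if n_in < 1 or n_out < 1:
            raise ValueError("n_in and n_out must be positive")
        self.n_in, self.n_out = n_in, n_out
        self.grid = grid if grid is not None else build_grid(-1.0, 1.0, 5, 3)
        if base_activation not in ACTIVATIONS:
            raise ValueError(f"unknown base activation {base_activation!r}")
        self.base_activation = base_activation
        self.use_scaler = use_scaler
        self.clamp_inputs = clamp_inputs
        d = self.grid.basis_dim
        rng = rng_for(seed, name)
        bound = float(np.sqrt(6.0 / n_in))
        self.base_weight = Parameter(rng.uniform(-bound, bound, size=(n_out, n_in)))
        # small-noise spline init scaled by the basis dimension
        self.spline_weight = Parameter(rng.normal(0.0, 0.1 / d, size=(n_out, n_in, d)))
        if use_scaler:
            self.spline_scaler = Parameter(np.ones((n_out, n_in)))

    def forward(self, x: Tensor) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(x)
        if x.ndim != 2 or x.shape[1] != self.n_in:
            raise ValueError(f"expected (batch, {self.n_in}) input, got {x.shape}")
        _check_finite(x.data, "input")
        b, d = x.shape[0], self.grid.basis_dim
        act = ACTIVATIONS[self.base_activation]
        y = act(x) @ self.base_weight.T
        basis = bspline_basis_tensor(x.reshape(b * self.n_in), self.grid,
                                     clamp=self.clamp_inputs)
        if self.use_scaler:
            w = self.spline_scaler.reshape(self.n_out, self.n_in, 1) * self.spline_weight
        else:
            w = self.spline_weight
        w = w.reshape(self.n_out, self.n_in * d)
        return y + basis.reshape(b, self.n_in * d) @ w.T


class ConvKAN(Module):
    """1-D convolution whose every kernel tap is a univariate spline function.

    Output position p of channel o is
    sum_c sum_t phi_{o,c,t}(x[c, p*stride + t - padding]), realized by
    unfolding sliding windows and applying the linear-KAN kernel to the
    (channels * kernel_size)-dimensional window vectors.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 grid: SplineGrid | None = None, stride: int = 1, padding: int = 0,
                 base_activation: str = "silu", use_scaler: bool = False,
                 clamp_inputs: bool = False, seed: int = 0, name: str = "ckan"):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        self.grid = grid if grid is not None else build_grid(-1.0, 1.0, 5, 3)
        if base_activation not in ACTIVATIONS:
            raise ValueError(f"unknown base activation {base_activation!r}")
        self.base_activation = base_activation
        self.use_scaler = use_scaler
        self.clamp_inputs = clamp_inputs
        d = self.grid.basis_dim
        k = kernel_size
        rng = rng_for(seed, name)
        fan_in = in_channels * k
        bound = float(np.sqrt(6.0 / fan_in))
        self.base_weight = Parameter(
            rng.uniform(-bound, bound, size=(out_channels, in_channels, k)))
        self.spline_weight = Parameter(
            rng.normal(0.0, 0.1 / d, size=(out_channels, in_channels, k, d)))
        if use_scaler:
            self.spline_scaler = Parameter(np.ones((out_channels, in_channels, k)))

    def out_length(self, length: int) -> int:
        return (length + 2 * self.padding - self.kernel_size) // self.stride + 1

    def forward(self, x: Tensor) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(x)
        if x.ndim != 3 or x.shape[1] != self.in_channels:
            raise ValueError(
                f"expected (batch, {self.in_channels}, L) input, got {x.shape}")
        _check_finite(x.data, "input")
        b, c, length = x.shape
        if length + 2 * self.padding < self.kernel_size:
            raise ValueError("kernel larger than padded input")
        k, d = self.kernel_size, self.grid.basis_dim
        # Pad once, then run zero-padding convolutions over the padded signal:
        # padded positions contribute phi(0) exactly as window-unfolding would.
        xp = x.pad_last(self.padding, self.padding)
        lp = length + 2 * self.padding
        act = ACTIVATIONS[self.base_activation]
        y = act(xp).conv1d(self.base_weight, stride=self.stride)
        # basis maps: one channel per (input channel, basis function)
        basis = bspline_basis_tensor(xp.reshape(b * c * lp), self.grid,
                                     clamp=self.clamp_inputs)
        maps = basis.reshape(b, c, lp, d).transpose(0, 1, 3, 2).reshape(b, c * d, lp)
        if self.use_scaler:
            w = self.spline_scaler.reshape(self.out_channels, c, k, 1) * self.spline_weight
        else:
            w = self.spline_weight
        # (o, c, k, d) -> (o, c*d, k) to convolve over the expanded channels
        w = w.transpose(0, 1, 3, 2).reshape(self.out_channels, c * d, k)
        return y + maps.conv1d(w, stride=self.stride)


def linear_kan_forward(x, layer: LinearKAN) -> Tensor:
    """Functional forward for a linear KAN layer (arrays accepted)."""
    return layer(x if isinstance(x, Tensor) else Tensor(x))


def conv_kan_forward(x, layer: ConvKAN) -> Tensor:
    """Functional forward for a convolutional KAN layer (arrays accepted)."""
    return layer(x if isinstance(x, Tensor) else Tensor(x))


def kan_regularization(layer: LinearKAN | ConvKAN, l1_weight: float = 1.0,
                       entropy_weight: float = 0.0) -> Tensor:
    """Sparsity penalty on the spline coefficients.

    Returns ``l1_weight * mean(|c|) + entropy_weight * H(p)`` where p is the
    distribution of per-edge L1 norms; H is zero when every coefficient is
    zero, so the whole penalty vanishes iff the spline branch does.
    Differentiable; meant to be added to the training loss.
    """
    if l1_weight < 0 or entropy_weight < 0:
        raise ValueError("penalty weights must be nonnegative")
    coeffs = layer.spline_weight.abs()
    out = l1_weight * coeffs.mean()
    if entropy_weight > 0:
        # per-edge L1 norm: sum over the trailing basis axis
        norms = coeffs.sum(axis=coeffs.ndim - 1)
        flat = norms.reshape(norms.size)
        total = flat.sum()
        if total.item() > 0:
            p = flat / total
            eps = 1e-12
            entropy = -(p * (p + eps).log()).sum()
            out = out + entropy_weight * entropy
    return out


# -- parameter accounting ---------------------------------------------------

def linear_kan_param_count(n_in: int, n_out: int, grid_size: int, degree: int,
                           use_scaler: bool = True) -> int:
    """Closed-form trainable count: n_out*n_in*(G+k) + base (+ scaler)."""
    d = grid_size + degree
    count = n_out * n_in * d + n_out * n_in
    if use_scaler:
        count += n_out * n_in
    return count


def conv_kan_param_count(in_channels: int, out_channels: int, kernel_size: int,
                         grid_size: int, degree: int, use_scaler: bool = False) -> int:
    d = grid_size + degree
    edges = out_channels * in_channels * kernel_size
    count = edges * d + edges
    if use_scaler:
        count += edges
    return count


def count_parameters(spec) -> int:
    """Exact trainable scalar count for a layer or a whole model."""
    if isinstance(spec, Module):
        return spec.num_parameters()
    raise TypeError(f"cannot count parameters of {type(spec).__name__}")


# -- FLOP accounting --------------------------------------------------------
#
# Convention: one fused multiply-add = 1 FLOP; bias additions and pointwise
# activations are excluded; the B-spline basis is charged (k+1)*k recursion
# steps per evaluated input scalar.

def _basis_cost(degree: int) -> int:
    return (degree + 1) * degree


def estimate_flops(layer: Module, input_shape: tuple) -> int:
    """Analytic multiply-add count of one forward pass for ``layer``.

    ``input_shape`` is the full input shape including the batch axis.
    """
    if isinstance(layer, Dense):
        batch = int(np.prod(input_shape[:-1]))
        return batch * layer.n_in * layer.n_out
    if isinstance(layer, Conv1d):
        batch, _, length = input_shape
        l_out = (length + 2 * layer.padding - layer.kernel_size) // layer.stride + 1
        return batch * layer.in_channels * layer.out_channels * layer.kernel_size * l_out
    if isinstance(layer, LinearKAN):
        batch = int(np.prod(input_shape[:-1]))
        d = layer.grid.basis_dim
        scalars = batch * layer.n_in
        base = batch * layer.n_in * layer.n_out
        spline = batch * layer.n_in * d * layer.n_out
        return scalars * _basis_cost(layer.grid.degree) + base + spline
    if isinstance(layer, ConvKAN):
        batch, _, length = input_shape
        l_out = layer.out_length(length)
        d = layer.grid.basis_dim
        window = layer.in_channels * layer.kernel_size
        scalars = batch * l_out * window
        base = batch * l_out * window * layer.out_channels
        spline = batch * l_out * window * d * layer.out_channels
        return scalars * _basis_cost(layer.grid.degree) + base + spline
    raise TypeError(f"no FLOP model for {type(layer).__name__}")
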