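"""Linear/convolutional KAN layers: oracles, reduction limits, accounting."""

import numpy as np
import pytest

from gkan.autograd import Tensor, grad
from gkan.kan_layers import (ConvKAN, LinearKAN, conv_kan_param_count,
                             count_parameters, estimate_flops,
                             kan_regularization, linear_kan_param_count)
from gkan.nn import Conv1d, Dense
from gkan.splines import build_grid
from _oracles import conv_kan_oracle, linear_kan_oracle, numerical_grad


class TestReductionLimit:
    def test_linear_kan_reduces_to_dense(self):
        """Zero spline branch + identity base activation = plain linear map."""
        rng = np.random.default_rng(0)
        layer = LinearKAN(5, 3, base_activation="identity", seed=1)
        layer.spline_weight.data[:] = 0.0
        dense = Dense(5, 3, bias=False, seed=2)
        dense.weight.data = layer.base_weight.data.copy()
        x = rng.normal(size=(7, 5))
        assert np.array_equal(layer(Tensor(x)).data, dense(Tensor(x)).data)

    def test_conv_kan_reduces_to_standard_conv(self):
        rng = np.random.default_rng(1)
        layer = ConvKAN(3, 4, 5, padding=2, base_activation="identity", seed=3)
        layer.spline_weight.data[:] = 0.0
        conv = Conv1d(3, 4, 5, padding=2, bias=False, seed=4)
        conv.weight.data = layer.base_weight.data.copy()
        x = rng.normal(size=(2, 3, 12))
        assert np.allclose(layer(Tensor(x)).data, conv(Tensor(x)).data,
                           atol=0, rtol=0)


class TestOracleEquivalence:
    def test_linear_kan_matches_per_edge_loop(self, rng):
        for trial in range(8):
            n_in = int(rng.integers(1, 5))
            n_out = int(rng.integers(1, 4))
            g = build_grid(-1, 1, int(rng.integers(1, 8)), int(rng.integers(0, 4)))
            layer = LinearKAN(n_in, n_out, grid=g, seed=trial,
                              use_scaler=bool(trial % 2))
            x = rng.uniform(-1.4, 1.4, size=(4, n_in))
            assert np.abs(layer(Tensor(x)).data
                          - linear_kan_oracle(x, layer)).max() < 1e-6

    def test_conv_kan_matches_sliding_window_loop(self, rng):
        for trial in range(6):
            c_in = int(rng.integers(1, 4))
            c_out = int(rng.integers(1, 4))
            k = int(rng.integers(1, 4))
            pad = int(rng.integers(0, 3))
            stride = int(rng.integers(1, 3))
            g = build_grid(-1, 1, int(rng.integers(1, 7)), int(rng.integers(0, 4)))
            layer = ConvKAN(c_in, c_out, k, grid=g, padding=pad, stride=stride,
                            seed=trial, use_scaler=bool(trial % 2))
            x = rng.uniform(-1.2, 1.2, size=(2, c_in, 11))
            assert np.abs(layer(Tensor(x)).data
                          - conv_kan_oracle(x, layer)).max() < 1e-6


class TestGradients:
    def test_linear_kan_gradcheck(self):
        layer = LinearKAN(3, 2, grid=build_grid(-1, 1, 3, 2), seed=5)
        x = np.random.default_rng(5).uniform(-0.9, 0.9, size=(4, 3))
        tgt = np.random.default_rng(6).normal(size=(4, 2))

        def loss():
            return (((layer(Tensor(x)) - Tensor(tgt)) ** 2.0).mean())

        params = {k: p for k, p in layer.named_parameters()}
        gs = grad(loss(), list(params.values()))
        for (name, p), g in zip(params.items(), gs):
            def f(v, p=p):
                old = p.data.copy()
                p.data = v
                out = loss().item()
                p.data = old
                return out
            num = numerical_grad(f, p.data.copy())
            denom = np.maximum(np.abs(num), 1e-3)
            assert np.max(np.abs(g.data - num) / denom) < 1e-4, name

    def test_conv_kan_gradcheck(self):
        layer = ConvKAN(2, 2, 3, grid=build_grid(-1, 1, 3, 2), padding=1, seed=7)
        x = np.random.default_rng(7).uniform(-0.9, 0.9, size=(2, 2, 6))

        def loss():
            return (layer(Tensor(x)) ** 2.0).mean()

        params = {k: p for k, p in layer.named_parameters()}
        gs = grad(loss(), list(params.values()))
        for (name, p), g in zip(params.items(), gs):
            def f(v, p=p):
                old = p.data.copy()
                p.data = v
                out = loss().item()
                p.data = old
                return out
            num = numerical_grad(f, p.data.copy())
            denom = np.maximum(np.abs(num), 1e-3)
            assert np.max(np.abs(g.data - num) / denom) < 1e-4, name


class TestRegularization:
    def test_zero_spline_weights_give_zero_penalty(self):
        layer = LinearKAN(3, 2, seed=0)
        layer.spline_weight.data[:] = 0.0
        assert kan_regularization(layer, 1.0, 1.0).item() == 0.0

    def test_single_coefficient_l1(self):
        layer = LinearKAN(2, 2, grid=build_grid(-1, 1, 2, 1), seed=0)
        layer.spline_weight.data[:] = 0.0
        layer.spline_weight.data[1, 0, 2] = -0.7
        n = layer.spline_weight.size
        assert kan_regularization(layer, 1.0, 0.0).item() == pytest.approx(0.7 / n)

    def test_uniform_coefficients_entropy_is_log_edges(self):
        layer = LinearKAN(3, 4, seed=0)
        layer.spline_weight.data[:] = 0.25
        n_edges = 3 * 4
        val = kan_regularization(layer, 0.0, 1.0).item()
        assert val == pytest.approx(np.log(n_edges), rel=1e-6)

    def test_negative_penalty_weights_rejected(self):
        layer = LinearKAN(2, 2, seed=0)
        with pytest.raises(ValueError):
            kan_regularization(layer, -1.0, 0.0)


class TestParameterAccounting:
    def test_linear_kan_closed_formula(self):
        layer = LinearKAN(4, 8, grid=build_grid(-1, 1, 5, 3), use_scaler=True)
        assert count_parameters(layer) == 4 * 8 * 8 + 32 + 32 == 320
        assert linear_kan_param_count(4, 8, 5, 3, True) == 320

    def test_dense_layer_count(self):
        assert count_parameters(Dense(4, 8)) == 40

    def test_count_affine_in_grid_size(self):
        base = None
        for G in [2, 5, 10, 16]:
            c = linear_kan_param_count(4, 8, G, 3, True)
            layer = LinearKAN(4, 8, grid=build_grid(-1, 1, G, 3))
            assert count_parameters(layer) == c
            if base is not None:
                g0, c0 = base
                assert (c - c0) == 4 * 8 * (G - g0)  # slope n_in * n_out
            base = (G, c)

    def test_conv_kan_count(self):
        layer = ConvKAN(3, 4, 5, grid=build_grid(-1, 1, 5, 3))
        assert count_parameters(layer) == conv_kan_param_count(3, 4, 5, 5, 3)
        assert count_parameters(layer) == 3 * 4 * 5 * 8 + 3 * 4 * 5


class TestFlops:
    def test_dense_count(self):
        assert estimate_flops(Dense(4, 8), (1, 4)) == 32

    def test_conv_closed_form(self):
        conv = Conv1d(4, 4, 5, padding=2)
        assert estimate_flops(conv, (1, 4, 500)) == 4 * 4 * 5 * 500

    def test_kan_layers_cost_more_than_standard(self):
        for G in [1, 5, 10]:
            lk = LinearKAN(4, 8, grid=build_grid(-1, 1, G, 3))
            assert estimate_flops(lk, (1, 4)) > estimate_flops(Dense(4, 8), (1, 4))
            ck = ConvKAN(4, 4, 5, grid=build_grid(-1, 1, G, 3), padding=2)
            assert estimate_flops(ck, (1, 4, 100)) > estimate_flops(
                Conv1d(4, 4, 5, padding=2), (1, 4, 100))

    def test_kan_ratio_constant_in_batch_increasing_in_grid(self):
        def ratio(batch, G):
            lk = LinearKAN(4, 8, grid=build_grid(-1, 1, G, 3))
            return estimate_flops(lk, (batch, 4)) / estimate_flops(
                Dense(4, 8), (batch, 4))
        assert ratio(1, 5) == ratio(16, 5) == ratio(128, 5)
        assert ratio(1, 3) < ratio(1, 8) < ratio(1, 16)


class TestValidation:
    def test_shape_mismatch_rejected(self):
        layer = LinearKAN(3, 2, seed=0)
        with pytest.raises(ValueError):
            layer(Tensor(np.zeros((4, 5))))

    def test_non_finite_input_rejected(self):
        layer = LinearKAN(2, 2, seed=0)
        with pytest.raises(ValueError):
            layer(Tensor(np.array([[np.nan, 1.0]])))

    def test_kernel_larger_than_padded_input_rejected(self):
        layer = ConvKAN(2, 2, 7, padding=0, seed=0)
        with pytest.raises(ValueError):
            layer(Tensor(np.zeros((1, 2, 5))))

    def test_conv_output_length_formula(self):
        layer = ConvKAN(4, 3, 5, padding=2, seed=0)
        y = layer(Tensor(np.random.default_rng(0).uniform(-1, 1, (1, 4, 20))))
        assert y.shape == (1, 3, 20)  # "same" convolution: 5-wide, padding 2

    def test_all_zero_coefficients_give_zero_output(self):
        layer = ConvKAN(2, 3, 3, padding=1, base_activation="identity", seed=0)
        layer.spline_weight.data[:] = 0.0
        layer.base_weight.data[:] = 0.0
        y = layer(Tensor(np.random.default_rng(1).normal(size=(2, 2, 9))))
        assert np.array_equal(y.data, np.zeros((2, 3, 9)))
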