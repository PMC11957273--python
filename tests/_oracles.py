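"""Independent brute-force reference implementations used by the tests.

Everything here is deliberately written the slow, obvious way (recursive
definitions, explicit loops) so it shares no code path with the package.
"""

import numpy as np


def cox_de_boor(x: float, knots, m: int, k: int) -> float:
    """Textbook recursive B-spline basis function B_{m,k}(x)."""
    if k == 0:
        return 1.0 if knots[m] <= x < knots[m + 1] else 0.0
    left, right = 0.0, 0.0
    d1 = knots[m + k] - knots[m]
    if d1 > 0:
        left = (x - knots[m]) / d1 * cox_de_boor(x, knots, m, k - 1)
    d2 = knots[m + k + 1] - knots[m + 1]
    if d2 > 0:
        right = (knots[m + k + 1] - x) / d2 * cox_de_boor(x, knots, m + 1, k - 1)
    return left + right


def basis_row(x: float, grid) -> np.ndarray:
    """All basis values at one x via the recursive definition."""
    n = grid.basis_dim
    return np.array([cox_de_boor(x, grid.knots, m, grid.degree) for m in range(n)])


def linear_kan_oracle(x, layer):
    """Per-edge quadruple loop over (batch, out, in, basis)."""
    import numpy as np
    b, n_in = x.shape
    n_out = layer.n_out
    d = layer.grid.basis_dim
    sw = layer.spline_weight.data
    bw = layer.base_weight.data
    sc = layer.spline_scaler.data if layer.use_scaler else np.ones((n_out, n_in))
    out = np.zeros((b, n_out))
    for bi in range(b):
        for j in range(n_out):
            for i in range(n_in):
                xi = x[bi, i]
                out[bi, j] += bw[j, i] * _activate(layer.base_activation, xi)
                basis = basis_row(xi, layer.grid)
                out[bi, j] += sc[j, i] * float(np.dot(sw[j, i], basis))
    return out


def conv_kan_oracle(x, layer):
    """Naive sliding-window sum of per-tap edge functions phi_{o,c,t}."""
    b, c, L = x.shape
    k, s, p = layer.kernel_size, layer.stride, layer.padding
    l_out = (L + 2 * p - k) // s + 1
    xp = np.pad(x, ((0, 0), (0, 0), (p, p)))
    sw = layer.spline_weight.data
    bw = layer.base_weight.data
    sc = (layer.spline_scaler.data if layer.use_scaler
          else np.ones((layer.out_channels, c, k)))
    out = np.zeros((b, layer.out_channels, l_out))
    for bi in range(b):
        for o in range(layer.out_channels):
            for pos in range(l_out):
                acc = 0.0
                for ci in range(c):
                    for t in range(k):
                        v = xp[bi, ci, pos * s + t]
                        acc += bw[o, ci, t] * _activate(layer.base_activation, v)
                        basis = basis_row(v, layer.grid)
                        acc += sc[o, ci, t] * float(np.dot(sw[o, ci, t], basis))
                out[bi, o, pos] = acc
    return out


def _activate(name: str, v: float) -> float:
    if name == "silu":
        return v / (1.0 + np.exp(-v))
    if name == "relu":
        return max(v, 0.0)
    if name == "identity":
        return v
    if name == "sigmoid":
        return 1.0 / (1.0 + np.exp(-v))
    if name == "tanh":
        return float(np.tanh(v))
    raise ValueError(name)


def levenshtein_dp(a: str, b: str) -> int:
    """Full dynamic-programming edit-distance matrix."""
    n, m = len(a), len(b)
    dp = np.zeros((n + 1, m + 1), dtype=int)
    dp[:, 0] = np.arange(n + 1)
    dp[0, :] = np.arange(m + 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            dp[i, j] = min(dp[i - 1, j] + 1, dp[i, j - 1] + 1,
                           dp[i - 1, j - 1] + cost)
    return int(dp[n, m])


def mcc_from_vectors(tp: int, fn: int, fp: int, tn: int) -> float:
    """Pearson correlation of the expanded prediction/label vectors."""
    y = np.array([1] * tp + [1] * fn + [0] * fp + [0] * tn, dtype=float)
    p = np.array([1] * tp + [0] * fn + [1] * fp + [0] * tn, dtype=float)
    if y.std() == 0 or p.std() == 0:
        return 0.0
    return float(np.corrcoef(y, p)[0, 1])


def alternation_scan_score(seq: str, window: int = 24) -> int:
    """Best-window count of purine/pyrimidine alternation steps (Z-DNA scan)."""
    ry = np.array([1 if b in "AG" else 0 for b in seq])
    steps = (ry[1:] != ry[:-1]).astype(int)
    if len(steps) < window - 1:
        return int(steps.sum())
    c = np.concatenate([[0], np.cumsum(steps)])
    w = window - 1
    return int(max(c[w:] - c[:-w]))


def numerical_grad(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central finite differences of a scalar function of an array."""
    g = np.zeros_like(x, dtype=float)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        xp = x.copy(); xp[i] += eps
        xm = x.copy(); xm[i] -= eps
        g[i] = (f(xp) - f(xm)) / (2 * eps)
        it.iternext()
    return g
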