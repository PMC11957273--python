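"""Minimal neural-network module system over :mod:`gkan.autograd`.

Provides the standard layers the classifier and GAN scaffolds are built
from (dense, 1-D convolution, batch norm, activations, pooling) plus
parameter bookkeeping, deterministic per-layer initialization and a
text-manifest / checkpoint facility.  KAN layers live in
:mod:`gkan.kan_layers` and subclass :class:`Module`.
"""

from __future__ import annotations

import hashlib
import json
import os
from typing import Iterator

import numpy as np

from .autograd import Tensor, no_grad

__all__ = [
    "Module", "Parameter", "Dense", "Conv1d", "BatchNorm1d", "Sequential",
    "ReLU", "SiLU", "Sigmoid", "Identity", "GlobalAvgPool1d", "Flatten",
    "rng_for", "save_checkpoint", "load_checkpoint",
]


def rng_for(seed: int, name: str) -> np.random.Generator:
    """Deterministic per-layer RNG derived from a global seed and a layer path.

    Keying the stream on the layer's name (not on construction order) means
    that swapping one sub-layer for a KAN variant leaves every other layer's
    initialization bit-for-bit unchanged — which is what makes
    baseline-vs-variant comparisons differ only where the architecture does.
    """
    h = hashlib.sha256(f"{seed}:{name}".encode()).digest()
    return np.random.default_rng(int.from_bytes(h[:8], "little") % (2**63))


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class with parameter/submodule registration by attribute."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, key, value):
        if isinstance(value, Parameter):
            self._params[key] = value
        elif isinstance(value, Module):
            self._modules[key] = value
        object.__setattr__(self, key, value)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    # -- traversal --------------------------------------------------------
    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for k, p in self._params.items():
            yield (f"{prefix}{k}", p)
        for k, m in self._modules.items():
            yield from m.named_parameters(prefix=f"{prefix}{k}.")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_modules(self, prefix: str = "") -> Iterator[tuple[str, "Module"]]:
        yield (prefix.rstrip("."), self)
        for k, m in self._modules.items():
            yield from m.named_modules(prefix=f"{prefix}{k}.")

    def train(self, mode: bool = True):
        object.__setattr__(self, "training", mode)
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- bookkeeping ------------------------------------------------------
    def num_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {k: p.data.copy() for k, p in self.named_parameters()}
        for name, m in self.named_modules():
            for bk, bv in getattr(m, "_buffers", {}).items():
                state[f"{name}.{bk}".lstrip(".")] = bv.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        own = dict(self.named_parameters())
        buffers = {}
        for name, m in self.named_modules():
            for bk in getattr(m, "_buffers", {}):
                buffers[f"{name}.{bk}".lstrip(".")] = (m, bk)
        for k, v in state.items():
            if k in own:
                if own[k].data.shape != v.shape:
                    raise ValueError(f"shape mismatch for {k}")
                own[k].data = np.array(v, dtype=np.float64)
            elif k in buffers:
                m, bk = buffers[k]
                m._buffers[bk] = np.array(v, dtype=np.float64)
            else:
                raise KeyError(f"unexpected key {k}")

    def manifest(self) -> list[str]:
        """One line per leaf module: name, type, parameter shapes and count."""
        lines = []
        for name, m in self.named_modules():
            if m._modules:
                continue
            shapes = ",".join(
                f"{k}:{'x'.join(map(str, p.shape))}" for k, p in m._params.items()
            )
            lines.append(f"{name or '.'}\t{type(m).__name__}\t{shapes}\t{m.num_parameters()}")
        return lines


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        for i, layer in enumerate(layers):
            setattr(self, f"l{i}", layer)
        self.layers = list(layers)

    def __setattr__(self, key, value):  # keep plain list attribute unregistered
        if key == "layers":
            object.__setattr__(self, key, value)
        else:
            super().__setattr__(key, value)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class Dense(Module):
    """Fully connected layer y = x W^T + b."""

    def __init__(self, n_in: int, n_out: int, bias: bool = True,
                 seed: int = 0, name: str = "dense"):
        super().__init__()
        self.n_in, self.n_out, self.has_bias = n_in, n_out, bias
        rng = rng_for(seed, name)
        bound = float(np.sqrt(6.0 / n_in))  # variance-preserving uniform
        self.weight = Parameter(rng.uniform(-bound, bound, size=(n_out, n_in)))
        if bias:
            self.bias = Parameter(np.zeros(n_out))

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight.T
        if self.has_bias:
            y = y + self.bias
        return y


class Conv1d(Module):
    """Standard 1-D convolution over (batch, channels, length) tensors."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, bias: bool = True,
                 seed: int = 0, name: str = "conv"):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        self.has_bias = bias
        rng = rng_for(seed, name)
        fan_in = in_channels * kernel_size
        bound = float(np.sqrt(6.0 / fan_in))
        self.weight = Parameter(
            rng.uniform(-bound, bound, size=(out_channels, in_channels, kernel_size))
        )
        if bias:
            self.bias = Parameter(np.zeros(out_channels))

    def forward(self, x: Tensor) -> Tensor:
        b, c, length = x.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} channels, got {c}")
        if length + 2 * self.padding < self.kernel_size:
            raise ValueError("kernel larger than padded input")
        y = x.conv1d(self.weight, stride=self.stride, padding=self.padding)
        if self.has_bias:
            y = y + self.bias.reshape(1, self.out_channels, 1)
        return y


class BatchNorm1d(Module):
    """Batch normalization over (batch, channels, length) or (batch, features)."""

    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.num_features = num_features
        self.momentum = momentum
        self.eps = eps
        self.gamma = Parameter(np.ones(num_features))
        self.beta = Parameter(np.zeros(num_features))
        object.__setattr__(self, "_buffers", {
            "running_mean": np.zeros(num_features),
            "running_var": np.ones(num_features),
        })

    def forward(self, x: Tensor) -> Tensor:
        if x.ndim == 3:
            axes, shape = (0, 2), (1, self.num_features, 1)
        else:
            axes, shape = (0,), (1, self.num_features)
        if self.training:
            mu = x.mean(axis=axes, keepdims=True)
            var = ((x - mu) ** 2.0).mean(axis=axes, keepdims=True)
            m = self.momentum
            self._buffers["running_mean"] *= (1 - m)
            self._buffers["running_mean"] += m * mu.data.reshape(-1)
            self._buffers["running_var"] *= (1 - m)
            self._buffers["running_var"] += m * var.data.reshape(-1)
        else:
            mu = Tensor(self._buffers["running_mean"].reshape(shape))
            var = Tensor(self._buffers["running_var"].reshape(shape))
        xhat = (x - mu) * ((var + self.eps) ** -0.5)
        return xhat * self.gamma.reshape(shape) + self.beta.reshape(shape)


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class SiLU(Module):
    def forward(self, x):
        return x.silu()


class Sigmoid(Module):
    def forward(self, x):
        return x.sigmoid()


class Identity(Module):
    def forward(self, x):
        return x


class GlobalAvgPool1d(Module):
    def forward(self, x):
        return x.mean(axis=2)


class Flatten(Module):
    def forward(self, x):
        return x.reshape(x.shape[0], int(np.prod(x.shape[1:])))


# -- activations by name --------------------------------------------------

ACTIVATIONS = {
    "silu": lambda x: x.silu(),
    "relu": lambda x: x.relu(),
    "sigmoid": lambda x: x.sigmoid(),
    "tanh": lambda x: x.tanh(),
    "identity": lambda x: x,
}


# -- checkpointing ---------------------------------------------------------

CHECKPOINT_VERSION = 1


def save_checkpoint(model: Module, directory: str, meta: dict | None = None):
    """Write a checkpoint: JSON manifest + one .npz tensor archive."""
    os.makedirs(directory, exist_ok=True)
    state = model.state_dict()
    manifest = {
        "version": CHECKPOINT_VERSION,
        "arrays": {k: list(v.shape) for k, v in state.items()},
        "layers": model.manifest(),
        "meta": meta or {},
    }
    with open(os.path.join(directory, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    np.savez(os.path.join(directory, "weights.npz"), **state)


def load_checkpoint(model: Module, directory: str) -> dict:
    with open(os.path.join(directory, "manifest.json")) as fh:
        manifest = json.load(fh)
    if manifest["version"] != CHECKPOINT_VERSION:
        raise ValueError(f"unsupported checkpoint version {manifest['version']}")
    with np.load(os.path.join(directory, "weights.npz")) as npz:
        model.load_state_dict({k: npz[k] for k in npz.files})
    return manifest.get("meta", {})
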