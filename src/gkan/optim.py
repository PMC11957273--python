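"""Optimizers and weight averaging for the numpy training stack."""

from __future__ import annotations

import numpy as np

from .nn import Module, Parameter

__all__ = ["AdamW", "EMA"]


class AdamW:
    """Adam with decoupled weight decay.

    Defaults (lr 1e-3, betas 0.9/0.999, eps 1e-8) follow common practice for
    sequence CNNs at small scale.
    """

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad.data
            if not np.all(np.isfinite(g)):
                raise FloatingPointError("non-finite gradient encountered")
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / bc1
            vhat = self.v[i] / bc2
            if self.weight_decay:
                p.data = p.data * (1.0 - self.lr * self.weight_decay)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


class EMA:
    """Exponential moving average of model weights.

    shadow <- decay * shadow + (1 - decay) * weights after every update;
    decay 0 tracks the raw weights exactly, decay -> 1 freezes the shadow at
    its initialization.  Evaluation swaps the shadow in and back out.
    """

    def __init__(self, model: Module, decay: float):
        if not (0.0 <= decay < 1.0):
            raise ValueError("decay must be in [0, 1)")
        self.decay = decay
        self.model = model
        self.shadow = {k: p.data.copy() for k, p in model.named_parameters()}

    def update(self):
        d = self.decay
        for k, p in self.model.named_parameters():
            self.shadow[k] = d * self.shadow[k] + (1.0 - d) * p.data

    def swap_in(self) -> dict[str, np.ndarray]:
        backup = {}
        for k, p in self.model.named_parameters():
            backup[k] = p.data
            p.data = self.shadow[k].copy()
        return backup

    def swap_out(self, backup: dict[str, np.ndarray]):
        for k, p in self.model.named_parameters():
            p.data = backup[k]
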