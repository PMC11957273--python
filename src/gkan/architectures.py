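"""Classifier and GAN scaffolds with swappable KAN layers.

The classifier follows the LegNet recipe — a convolutional stem, a run of
EfficientNet-like residual blocks with squeeze-excitation (SE) mid-blocks,
a pointwise final block and a pooled dense head — in three variants:

* ``baseline``: standard dense and convolutional layers throughout;
* ``lkan``: the dense layers inside the SE mid-blocks of the last
  ``replaced_blocks`` blocks become linear KAN layers;
* ``ckan``: the stem and final convolutions become KAN convolutions.

Everything else (layer names, shapes, RNG streams) is identical across
variants, so two variants differ exactly where the architecture does —
assertable on the text layer manifest.

The generative side is a ResNet Wasserstein GAN: generator and critic each
carry five residual blocks of 5-wide, padding-2 convolutions with ReLU.
``lgan`` swaps the critic's dense head for linear KANs; ``cgan`` swaps the
residual-block convolutions for KAN convolutions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .autograd import Tensor, grad, no_grad
from .kan_layers import ConvKAN, LinearKAN, count_parameters
from .nn import (BatchNorm1d, Conv1d, Dense, GlobalAvgPool1d, Module,
                 SiLU, rng_for)
from .optim import AdamW
from .splines import build_grid

__all__ = [
    "ModelConfig", "GANConfig", "build_classifier", "build_gan",
    "match_parameter_budget", "wgan_train_step", "softmax_channels",
    "generate_sequences",
]

VARIANTS = ("baseline", "lkan", "ckan")


@dataclass
class ModelConfig:
    """Architecture variant and scale — the experiment's independent variables."""

    task: str = "classify"
    variant: str = "baseline"
    num_blocks: int = 6
    channels: tuple[int, ...] | None = None  # per-block widths; None -> uniform 32
    grid_size: int = 5
    spline_degree: int = 3
    replaced_blocks: int | None = None  # lkan only; None -> all blocks
    seq_length: int = 200
    num_classes: int = 2
    stem_kernel: int = 7
    block_kernel: int = 5
    se_reduction: int = 4
    base_activation: str = "silu"
    use_scaler: bool = True
    seed: int = 0

    def resolved_channels(self) -> tuple[int, ...]:
        if self.channels is None:
            return (32,) * self.num_blocks
        return tuple(self.channels)

    def resolved_replaced(self) -> int:
        if self.variant != "lkan":
            return 0
        return self.num_blocks if self.replaced_blocks is None else self.replaced_blocks

    def validate(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        ch = self.resolved_channels()
        if len(ch) != self.num_blocks:
            raise ValueError(
                f"channels has {len(ch)} entries for {self.num_blocks} blocks")
        if any(c < 1 for c in ch):
            raise ValueError("channel widths must be positive")
        if self.variant == "lkan":
            r = self.resolved_replaced()
            if not (0 <= r <= self.num_blocks):
                raise ValueError("replaced_blocks out of range")
        if self.seq_length < self.stem_kernel:
            raise ValueError("seq_length smaller than the stem kernel")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["channels"] is not None:
            d["channels"] = list(d["channels"])
        return d

    @staticmethod
    def from_dict(d: dict) -> "ModelConfig":
        d = dict(d)
        if d.get("channels") is not None:
            d["channels"] = tuple(d["channels"])
        return ModelConfig(**d)


@dataclass
class GANConfig:
    latent_dim: int = 64
    seq_length: int = 100
    base_channels: int = 32
    num_resnet_blocks: int = 5
    kernel_size: int = 5
    padding: int = 2
    variant: str = "wgan"
    critic_steps_per_generator_step: int = 5
    gradient_penalty_weight: float = 10.0
    weight_clip: float | None = None  # set to use original weight clipping
    grid_size: int = 5
    spline_degree: int = 3
    seed: int = 0

    def validate(self):
        if self.variant not in ("wgan", "lgan", "cgan"):
            raise ValueError(f"unknown GAN variant {self.variant!r}")
        if 2 * self.padding != self.kernel_size - 1:
            raise ValueError("blocks must preserve length: need 2*padding == kernel-1")


# -- squeeze-excitation mid-block ------------------------------------------

class SEBlock(Module):
    """Channel-reweighting block with a gated two-branch ("bilinear") layer.

    The pooled channel summary passes through two parallel linear maps whose
    elementwise product (one branch sigmoid-gated) forms the bottleneck,
    then expands back to a per-channel sigmoid scale.  In the LKAN variant
    all three linear maps are linear KAN layers.
    """

    def __init__(self, channels: int, reduction: int, kan: bool,
                 grid_size: int, degree: int, base_activation: str,
                 use_scaler: bool, seed: int, name: str):
        super().__init__()
        mid = max(1, channels // reduction)
        if kan:
            g = build_grid(-1.0, 1.0, grid_size, degree)
            self.fc_a = LinearKAN(channels, mid, grid=g, seed=seed,
                                  base_activation=base_activation,
                                  use_scaler=use_scaler, name=f"{name}.fc_a")
            self.fc_b = LinearKAN(channels, mid, grid=g, seed=seed,
                                  base_activation=base_activation,
                                  use_scaler=use_scaler, name=f"{name}.fc_b")
            self.fc_out = LinearKAN(mid, channels, grid=g, seed=seed,
                                    base_activation=base_activation,
                                    use_scaler=use_scaler, name=f"{name}.fc_out")
        else:
            self.fc_a = Dense(channels, mid, seed=seed, name=f"{name}.fc_a")
            self.fc_b = Dense(channels, mid, seed=seed, name=f"{name}.fc_b")
            self.fc_out = Dense(mid, channels, seed=seed, name=f"{name}.fc_out")

    def forward(self, x: Tensor) -> Tensor:
        z = x.mean(axis=2)  # (batch, channels)
        u = self.fc_a(z) * self.fc_b(z).sigmoid()
        s = self.fc_out(u).sigmoid()
        return x * s.reshape(s.shape[0], s.shape[1], 1)


class EffBlock(Module):
    """EfficientNet-like residual block: conv -> BN -> SiLU -> SE -> pointwise."""

    def __init__(self, c_in: int, c_out: int, kernel: int, se_kan: bool,
                 cfg: ModelConfig, seed: int, name: str):
        super().__init__()
        pad = kernel // 2
        self.conv = Conv1d(c_in, c_out, kernel, padding=pad, seed=seed,
                           name=f"{name}.conv")
        self.bn1 = BatchNorm1d(c_out)
        self.se = SEBlock(c_out, cfg.se_reduction, se_kan, cfg.grid_size,
                          cfg.spline_degree, cfg.base_activation,
                          cfg.use_scaler, seed, f"{name}.se")
        self.pw = Conv1d(c_out, c_out, 1, seed=seed, name=f"{name}.pw")
        self.bn2 = BatchNorm1d(c_out)
        if c_in != c_out:
            self.proj = Conv1d(c_in, c_out, 1, bias=False, seed=seed,
                               name=f"{name}.proj")
        else:
            self.proj = None

    def __setattr__(self, key, value):
        if key == "proj" and value is None:
            object.__setattr__(self, key, value)
        else:
            super().__setattr__(key, value)

    def forward(self, x: Tensor) -> Tensor:
        h = self.bn1(self.conv(x)).silu()
        h = self.se(h)
        h = self.bn2(self.pw(h)).silu()
        res = x if self.proj is None else self.proj(x)
        return h + res


class LegNetClassifier(Module):
    """LegNet-style CNN mapping one-hot (batch, 4, L) to class logits."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        cfg.validate()
        self.config = cfg
        ch = cfg.resolved_channels()
        seed = cfg.seed
        ckan = cfg.variant == "ckan"
        g = build_grid(-1.0, 1.0, cfg.grid_size, cfg.spline_degree)
        if ckan:
            self.stem = ConvKAN(4, ch[0], cfg.stem_kernel, grid=g,
                                padding=cfg.stem_kernel // 2, seed=seed,
                                base_activation=cfg.base_activation,
                                name="stem.conv")
        else:
            self.stem = Conv1d(4, ch[0], cfg.stem_kernel,
                               padding=cfg.stem_kernel // 2, seed=seed,
                               name="stem.conv")
        self.stem_bn = BatchNorm1d(ch[0])
        replaced = cfg.resolved_replaced()
        blocks = []
        c_prev = ch[0]
        for i, c in enumerate(ch):
            se_kan = cfg.variant == "lkan" and i >= cfg.num_blocks - replaced
            blocks.append(EffBlock(c_prev, c, cfg.block_kernel, se_kan, cfg,
                                   seed, f"block{i}"))
            c_prev = c
        for i, blk in enumerate(blocks):
            setattr(self, f"block{i}", blk)
        self.blocks = blocks
        if ckan:
            self.final = ConvKAN(c_prev, c_prev, 1, grid=g, seed=seed,
                                 base_activation=cfg.base_activation,
                                 name="final.conv")
        else:
            self.final = Conv1d(c_prev, c_prev, 1, seed=seed, name="final.conv")
        self.final_bn = BatchNorm1d(c_prev)
        self.head = Dense(c_prev, cfg.num_classes, seed=seed, name="head")

    def __setattr__(self, key, value):
        if key == "blocks":
            object.__setattr__(self, key, value)
        else:
            super().__setattr__(key, value)

    def forward(self, x) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(x)
        if x.ndim != 3 or x.shape[1] != 4:
            raise ValueError(f"expected (batch, 4, L) one-hot input, got {x.shape}")
        h = self.stem_bn(self.stem(x)).silu()
        for blk in self.blocks:
            h = blk(h)
        h = self.final_bn(self.final(h)).silu()
        return self.head(h.mean(axis=2))


def build_classifier(config: ModelConfig) -> LegNetClassifier:
    """Construct a classifier variant; deterministic under ``config.seed``."""
    return LegNetClassifier(config)


def match_parameter_budget(target_params: int, config_template: ModelConfig,
                           min_width: int = 4, tolerance: float = 0.02) -> ModelConfig:
    """Scale channel widths so the model's parameter count meets a budget.

    Binary-searches a scalar width multiplier and returns the config whose
    count is closest to ``target_params`` without exceeding it by more than
    ``tolerance`` (2% by default) — the fairness protocol that puts baseline
    and KAN variants at equal size.
    """
    base_ch = config_template.resolved_channels()

    def scaled(mult: float) -> ModelConfig:
        ch = tuple(max(min_width, int(round(c * mult))) for c in base_ch)
        return dataclasses.replace(config_template, channels=ch)

    def count(mult: float) -> int:
        return count_parameters(build_classifier(scaled(mult)))

    if count_parameters(build_classifier(config_template)) == target_params:
        return dataclasses.replace(config_template)

    lo, hi = 1e-2, 1.0
    if count(hi) < target_params:
        while count(hi) < target_params and hi < 256:
            hi *= 2.0
    if count(lo) > target_params * (1 + tolerance):
        raise ValueError(
            f"budget {target_params} below the minimum-width model size {count(lo)}")
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        if count(mid) <= target_params:
            lo = mid
        else:
            hi = mid
    best_cfg, best_gap = None, None
    for mult in sorted({lo * (1.0 + j / 200.0) for j in range(-4, 5)}):
        cfg = scaled(mult)
        c = count_parameters(build_classifier(cfg))
        if c > target_params * (1 + tolerance):
            continue
        gap = abs(c - target_params)
        if best_gap is None or gap < best_gap:
            best_cfg, best_gap = cfg, gap
    if best_cfg is None:
        raise ValueError(f"no configuration within {tolerance:.0%} of {target_params}")
    return best_cfg


# -- GAN -------------------------------------------------------------------

class ResBlock(Module):
    def __init__(self, channels: int, kernel: int, padding: int, kan: bool,
                 grid_size: int, degree: int, seed: int, name: str):
        super().__init__()
        if kan:
            g = build_grid(-1.0, 1.0, grid_size, degree)
            self.conv = ConvKAN(channels, channels, kernel, grid=g,
                                padding=padding, seed=seed, name=f"{name}.conv")
        else:
            self.conv = Conv1d(channels, channels, kernel, padding=padding,
                               seed=seed, name=f"{name}.conv")

    def forward(self, x: Tensor) -> Tensor:
        return x + self.conv(x).relu()


class Generator(Module):
    """Maps latent noise (batch, latent_dim) to nucleotide logits (batch, 4, L)."""

    def __init__(self, cfg: GANConfig):
        super().__init__()
        cfg.validate()
        self.config = cfg
        c, L = cfg.base_channels, cfg.seq_length
        kan = cfg.variant == "cgan"
        self.fc = Dense(cfg.latent_dim, c * L, seed=cfg.seed, name="gen.fc")
        blocks = [ResBlock(c, cfg.kernel_size, cfg.padding, kan, cfg.grid_size,
                           cfg.spline_degree, cfg.seed, f"gen.res{i}")
                  for i in range(cfg.num_resnet_blocks)]
        for i, blk in enumerate(blocks):
            setattr(self, f"res{i}", blk)
        self.blocks = blocks
        self.out_conv = Conv1d(c, 4, 1, seed=cfg.seed, name="gen.out")

    def __setattr__(self, key, value):
        if key == "blocks":
            object.__setattr__(self, key, value)
        else:
            super().__setattr__(key, value)

    def forward(self, z) -> Tensor:
        if not isinstance(z, Tensor):
            z = Tensor(z)
        cfg = self.config
        h = self.fc(z).relu()
        h = h.reshape(z.shape[0], cfg.base_channels, cfg.seq_length)
        for blk in self.blocks:
            h = blk(h)
        return self.out_conv(h)


class Critic(Module):
    """Scores sequences (one-hot or per-position probabilities) with a scalar."""

    def __init__(self, cfg: GANConfig):
        super().__init__()
        cfg.validate()
        self.config = cfg
        c = cfg.base_channels
        kan_conv = cfg.variant == "cgan"
        kan_head = cfg.variant == "lgan"
        self.stem = Conv1d(4, c, cfg.kernel_size, padding=cfg.padding,
                           seed=cfg.seed, name="critic.stem")
        blocks = [ResBlock(c, cfg.kernel_size, cfg.padding, kan_conv,
                           cfg.grid_size, cfg.spline_degree, cfg.seed,
                           f"critic.res{i}")
                  for i in range(cfg.num_resnet_blocks)]
        for i, blk in enumerate(blocks):
            setattr(self, f"res{i}", blk)
        self.blocks = blocks
        if kan_head:
            g = build_grid(-1.0, 1.0, cfg.grid_size, cfg.spline_degree)
            self.head1 = LinearKAN(c, c, grid=g, seed=cfg.seed, name="critic.head1")
            self.head2 = LinearKAN(c, 1, grid=g, seed=cfg.seed, name="critic.head2")
        else:
            self.head1 = Dense(c, c, seed=cfg.seed, name="critic.head1")
            self.head2 = Dense(c, 1, seed=cfg.seed, name="critic.head2")
        self.kan_head = kan_head

    def __setattr__(self, key, value):
        if key in ("blocks", "kan_head"):
            object.__setattr__(self, key, value)
        else:
            super().__setattr__(key, value)

    def forward(self, x) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(x)
        h = self.stem(x).relu()
        for blk in self.blocks:
            h = blk(h)
        h = h.mean(axis=2)
        h = self.head1(h)
        if not self.kan_head:
            h = h.relu()
        return self.head2(h)


def build_gan(config: GANConfig) -> tuple[Generator, Critic]:
    config.validate()
    return Generator(config), Critic(config)


def softmax_channels(x: Tensor) -> Tensor:
    """Per-position softmax over the 4 nucleotide channels."""
    shifted = x - x.max(axis=1, keepdims=True)
    e = shifted.exp()
    return e / e.sum(axis=1, keepdims=True)


def wgan_train_step(generator: Generator, critic: Critic, real_batch,
                    config: GANConfig, rng: np.random.Generator,
                    opt_gen: AdamW, opt_critic: AdamW) -> dict:
    """One WGAN round: several critic updates, then one generator update.

    The critic maximizes E[critic(real)] - E[critic(fake)]; by default a
    gradient penalty keeps it near 1-Lipschitz (weight clipping selectable via
    ``config.weight_clip``).  Returns the last critic loss, the generator
    loss, the penalty value and the Wasserstein estimate.
    """
    real = np.asarray(real_batch, dtype=np.float64)
    batch = real.shape[0]
    record = {}
    for _ in range(config.critic_steps_per_generator_step):
        z = rng.standard_normal((batch, config.latent_dim))
        with no_grad():
            fake = softmax_channels(generator(Tensor(z))).data
        c_real = critic(Tensor(real)).mean()
        c_fake = critic(Tensor(fake)).mean()
        w_est = c_real - c_fake
        loss_c = c_fake - c_real
        gp_value = 0.0
        if config.gradient_penalty_weight > 0 and config.weight_clip is None:
            eps = rng.uniform(size=(batch, 1, 1))
            xhat = Tensor(eps * real + (1 - eps) * fake, requires_grad=True)
            score = critic(xhat).sum()
            (gx,) = grad(score, [xhat], create_graph=True)
            norm = ((gx * gx).sum(axis=(1, 2)) + 1e-12).sqrt()
            gp = ((norm - 1.0) ** 2.0).mean()
            loss_c = loss_c + config.gradient_penalty_weight * gp
            gp_value = gp.item()
        critic.zero_grad()
        loss_c.backward()
        opt_critic.step()
        if config.weight_clip is not None:
            for p in critic.parameters():
                np.clip(p.data, -config.weight_clip, config.weight_clip, out=p.data)
        if not np.isfinite(loss_c.item()):
            raise FloatingPointError("critic loss diverged")
        record.update(critic_loss=loss_c.item(), gradient_penalty=gp_value,
                      wasserstein_estimate=w_est.item())
    z = rng.standard_normal((batch, config.latent_dim))
    fake = softmax_channels(generator(Tensor(z)))
    loss_g = -critic(fake).mean()
    generator.zero_grad()
    critic.zero_grad()
    loss_g.backward()
    opt_gen.step()
    if not np.isfinite(loss_g.item()):
        raise FloatingPointError("generator loss diverged")
    record["generator_loss"] = loss_g.item()
    return record


def generate_sequences(generator: Generator, n: int, rng: np.random.Generator,
                       mode: str = "argmax") -> list[str]:
    """Decode generated nucleotide logits to DNA strings.

    ``argmax`` takes the per-position maximum-probability base (deterministic
    given the noise); ``sample`` draws from the per-position categorical.
    """
    alphabet = np.array(list("ACGT"))
    cfg = generator.config
    out: list[str] = []
    bs = 64
    for start in range(0, n, bs):
        m = min(bs, n - start)
        z = rng.standard_normal((m, cfg.latent_dim))
        with no_grad():
            probs = softmax_channels(generator(Tensor(z))).data
        if mode == "argmax":
            idx = probs.argmax(axis=1)
        elif mode == "sample":
            u = rng.uniform(size=(m, 1, cfg.seq_length))
            idx = (probs.cumsum(axis=1) < u).sum(axis=1)
            idx = np.clip(idx, 0, 3)
        else:
            raise ValueError(f"unknown decoding mode {mode!r}")
        out.extend("".join(alphabet[row]) for row in idx)
    return out
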