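"""Classifier/GAN scaffolds: variant locality, determinism, budget matching."""

import dataclasses

import numpy as np
import pytest

from gkan.architectures import (GANConfig, ModelConfig, build_classifier,
                                build_gan, generate_sequences,
                                match_parameter_budget, softmax_channels,
                                wgan_train_step)
from gkan.autograd import Tensor, no_grad
from gkan.kan_layers import count_parameters, linear_kan_param_count
from gkan.optim import AdamW

SMALL = dict(num_blocks=2, channels=(8, 8), seq_length=50, seed=3)


def small_cfg(**kw):
    return ModelConfig(**{**SMALL, **kw})


class TestClassifierVariants:
    @pytest.mark.parametrize("variant", ["baseline", "lkan", "ckan"])
    def test_forward_shape_and_finiteness(self, variant):
        model = build_classifier(small_cfg(variant=variant))
        x = np.random.default_rng(0).integers(0, 2, size=(2, 4, 50)).astype(float)
        y = model(Tensor(x))
        assert y.shape == (2, 2)
        assert np.all(np.isfinite(y.data))

    def test_zero_replacements_is_the_baseline(self):
        base = build_classifier(small_cfg(variant="baseline"))
        lkan0 = build_classifier(small_cfg(variant="lkan", replaced_blocks=0))
        assert base.manifest() == lkan0.manifest()
        assert count_parameters(base) == count_parameters(lkan0)
        x = np.random.default_rng(1).integers(0, 2, size=(2, 4, 50)).astype(float)
        with no_grad():
            assert np.array_equal(base(Tensor(x)).data, lkan0(Tensor(x)).data)

    def test_lkan_surplus_matches_closed_formula(self):
        base = build_classifier(small_cfg(variant="baseline"))
        lkan = build_classifier(small_cfg(variant="lkan", replaced_blocks=2))
        c, red, G, k = 8, 4, 5, 3
        mid = max(1, c // red)
        dense_se = (c * mid + mid) * 2 + (mid * c + c)
        kan_se = (linear_kan_param_count(c, mid, G, k, True) * 2
                  + linear_kan_param_count(mid, c, G, k, True))
        expected_surplus = 2 * (kan_se - dense_se)  # both blocks replaced
        assert count_parameters(lkan) - count_parameters(base) == expected_surplus
        assert count_parameters(lkan) > count_parameters(base)

    def test_replacement_locality_in_manifest(self):
        base = build_classifier(small_cfg(variant="baseline")).manifest()
        lkan = build_classifier(small_cfg(variant="lkan")).manifest()
        ckan = build_classifier(small_cfg(variant="ckan")).manifest()
        diff_lkan = [a.split("\t")[0] for a, b in zip(base, lkan) if a != b]
        assert diff_lkan and all(".se." in name for name in diff_lkan)
        diff_ckan = [a.split("\t")[0] for a, b in zip(base, ckan) if a != b]
        assert set(diff_ckan) == {"stem", "final"}

    def test_deterministic_under_seed(self):
        a = build_classifier(small_cfg(variant="lkan"))
        b = build_classifier(small_cfg(variant="lkan"))
        for (ka, pa), (kb, pb) in zip(a.named_parameters(), b.named_parameters()):
            assert ka == kb and np.array_equal(pa.data, pb.data)
        x = np.random.default_rng(2).integers(0, 2, size=(2, 4, 50)).astype(float)
        with no_grad():
            assert np.array_equal(a(Tensor(x)).data, b(Tensor(x)).data)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            build_classifier(small_cfg(channels=(8,)))  # wrong length
        with pytest.raises(ValueError):
            build_classifier(small_cfg(variant="lkan", replaced_blocks=5))
        with pytest.raises(ValueError):
            build_classifier(small_cfg(seq_length=3))
        with pytest.raises(ValueError):
            build_classifier(small_cfg(variant="mlp"))


class TestBudgetMatching:
    def test_own_count_is_a_fixed_point(self):
        cfg = small_cfg()
        target = count_parameters(build_classifier(cfg))
        matched = match_parameter_budget(target, cfg)
        assert count_parameters(build_classifier(matched)) == target

    def test_baseline_and_lkan_equalized(self):
        target = 60_000
        base = match_parameter_budget(target, small_cfg(variant="baseline"))
        lkan = match_parameter_budget(target, small_cfg(variant="lkan"))
        nb = count_parameters(build_classifier(base))
        nl = count_parameters(build_classifier(lkan))
        assert abs(nb - nl) / target < 0.02
        assert nb <= target * 1.02 and nl <= target * 1.02

    def test_unachievable_budget_errors(self):
        with pytest.raises(ValueError, match="budget"):
            match_parameter_budget(10, small_cfg())


GAN_SMALL = dict(latent_dim=16, seq_length=30, base_channels=8,
                 num_resnet_blocks=2, seed=4)


class TestGAN:
    def test_generator_output_shape(self):
        gen, _ = build_gan(GANConfig(latent_dim=64, seq_length=100,
                                     base_channels=8, seed=0))
        z = np.random.default_rng(0).standard_normal((8, 64))
        with no_grad():
            assert gen(Tensor(z)).shape == (8, 4, 100)

    def test_per_position_softmax_normalized(self):
        gen, _ = build_gan(GANConfig(**GAN_SMALL))
        z = np.random.default_rng(1).standard_normal((3, 16))
        with no_grad():
            p = softmax_channels(gen(Tensor(z))).data
        assert np.abs(p.sum(axis=1) - 1.0).max() < 1e-6
        assert (p >= 0).all()

    def test_lgan_differs_only_in_critic_head(self):
        _, c_wgan = build_gan(GANConfig(**GAN_SMALL, variant="wgan"))
        _, c_lgan = build_gan(GANConfig(**GAN_SMALL, variant="lgan"))
        diff = [a.split("\t")[0] for a, b in zip(c_wgan.manifest(),
                                                 c_lgan.manifest()) if a != b]
        assert set(diff) == {"head1", "head2"}
        g_wgan, _ = build_gan(GANConfig(**GAN_SMALL, variant="wgan"))
        g_lgan, _ = build_gan(GANConfig(**GAN_SMALL, variant="lgan"))
        assert g_wgan.manifest() == g_lgan.manifest()

    def test_cgan_swaps_resnet_convolutions(self):
        g_wgan, c_wgan = build_gan(GANConfig(**GAN_SMALL, variant="wgan"))
        g_cgan, c_cgan = build_gan(GANConfig(**GAN_SMALL, variant="cgan"))
        for base, kan in [(g_wgan, g_cgan), (c_wgan, c_cgan)]:
            diff = [a.split("\t")[0] for a, b in zip(base.manifest(),
                                                     kan.manifest()) if a != b]
            assert diff and all(".conv" in n and "res" in n for n in diff)

    def test_identical_real_and_fake_score_zero_wasserstein(self):
        _, critic = build_gan(GANConfig(**GAN_SMALL))
        x = np.random.default_rng(2).uniform(size=(4, 4, 30))
        with no_grad():
            est = critic(Tensor(x)).mean().item() - critic(Tensor(x)).mean().item()
        assert est == 0.0

    def test_train_step_record_and_reproducibility(self):
        def run():
            cfg = GANConfig(**GAN_SMALL, critic_steps_per_generator_step=2)
            gen, critic = build_gan(cfg)
            og = AdamW(gen.parameters(), lr=1e-4)
            oc = AdamW(critic.parameters(), lr=1e-4)
            rng = np.random.default_rng(9)
            real = np.eye(4)[np.random.default_rng(3).integers(0, 4, (6, 30))]
            real = real.transpose(0, 2, 1)
            recs = [wgan_train_step(gen, critic, real, cfg, rng, og, oc)
                    for _ in range(3)]
            return recs
        a, b = run(), run()
        for ra, rb in zip(a, b):
            assert ra == rb
            assert ra["gradient_penalty"] >= 0.0
            assert np.isfinite(ra["critic_loss"])
            assert np.isfinite(ra["generator_loss"])

    def test_weight_clipping_mode(self):
        cfg = GANConfig(**GAN_SMALL, weight_clip=0.01,
                        critic_steps_per_generator_step=1)
        gen, critic = build_gan(cfg)
        og = AdamW(gen.parameters(), lr=1e-3)
        oc = AdamW(critic.parameters(), lr=1e-3)
        real = np.eye(4)[np.random.default_rng(4).integers(0, 4, (4, 30))]
        rec = wgan_train_step(gen, critic, real.transpose(0, 2, 1), cfg,
                              np.random.default_rng(0), og, oc)
        assert rec["gradient_penalty"] == 0.0
        assert all(np.abs(p.data).max() <= 0.01 for p in critic.parameters())

    def test_generated_sequences_decode(self):
        gen, _ = build_gan(GANConfig(**GAN_SMALL))
        seqs = generate_sequences(gen, 5, np.random.default_rng(0))
        assert len(seqs) == 5
        assert all(len(s) == 30 and set(s) <= set("ACGT") for s in seqs)
        sampled = generate_sequences(gen, 5, np.random.default_rng(0),
                                     mode="sample")
        assert all(len(s) == 30 for s in sampled)

    def test_length_preservation_invariant_enforced(self):
        with pytest.raises(ValueError, match="preserve length"):
            GANConfig(kernel_size=5, padding=1).validate()
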