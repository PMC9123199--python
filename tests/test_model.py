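"""Network architecture contracts and loss-function oracles."""

import math

import numpy as np
import pytest

from ganstrip.model import (
    Discriminator,
    DiscriminatorConfig,
    Generator,
    GeneratorConfig,
    build_discriminator,
    build_generator,
    l1_loss,
    load_checkpoint,
    loss_discriminator,
    loss_generator,
    save_checkpoint,
)
from ganstrip.nn import Adam


class ConstD:
    """Discriminator stub with a fixed output probability."""

    def __init__(self, p, patch_shape=(2, 2, 2)):
        self.p = p
        self.patch = patch_shape

    def forward(self, c, x, train=False):
        return np.full(self.patch, self.p, dtype=np.float32)


class TestGenerator:
    def test_bottleneck_shape_is_one(self):
        g = build_generator(GeneratorConfig(depth=4, base_filters=4),
                            (16, 16, 16), seed=0)
        g.forward(np.zeros((16, 16, 16), dtype=np.float32))
        assert g._skips[-1].shape[1:] == (1, 1, 1)

    @pytest.mark.parametrize("shape", [(16, 16, 16), (32, 16, 16),
                                       (8, 24, 16)])
    def test_output_shape_equals_input_shape(self, shape, rng):
        g = build_generator(GeneratorConfig(depth=3, base_filters=4),
                            shape, seed=1)
        out = g.forward(rng.standard_normal(shape).astype(np.float32))
        assert out.shape == shape

    def test_output_bounded(self, rng):
        g = build_generator(GeneratorConfig(depth=3, base_filters=4), seed=2)
        out = g.forward(5 * rng.standard_normal((16, 16, 16)))
        assert out.min() >= -1.0 and out.max() <= 1.0

    def test_indivisible_shape_names_axis(self):
        g = build_generator(GeneratorConfig(depth=4, base_filters=4), seed=0)
        with pytest.raises(ValueError, match="axis z"):
            g.forward(np.zeros((16, 16, 12), dtype=np.float32))
        with pytest.raises(ValueError, match="axis x"):
            build_generator(GeneratorConfig(depth=4, base_filters=4),
                            input_shape=(12, 16, 16))

    def test_parameter_count_increases_with_width(self):
        def n_params(base):
            g = build_generator(GeneratorConfig(depth=3, base_filters=base),
                                seed=0)
            return sum(p.size for l in g.layers() for p in l.params.values())
        assert n_params(8) > n_params(4)

    def test_dropout_capped_below_output_block(self):
        g = build_generator(GeneratorConfig(depth=3, base_filters=4,
                                            dropout_layers=3), seed=0)
        assert g.dec[-1]["drop"] is None


class TestDiscriminator:
    def test_patch_shape_by_stride_plan(self):
        cfg = DiscriminatorConfig(levels=4, base_filters=4)
        assert cfg.patch_shape((64, 64, 16)) == (4, 4, 1)
        assert cfg.patch_shape((64, 64, 64)) == (4, 4, 4)

    def test_forward_patch_and_probability_range(self, rng):
        d = build_discriminator(DiscriminatorConfig(levels=3, base_filters=4),
                                (16, 16, 16), seed=3)
        p = d.forward(rng.standard_normal((16, 16, 16)),
                      rng.standard_normal((16, 16, 16)))
        assert p.shape == (2, 2, 2)
        assert np.all((p > 0) & (p < 1))

    def test_candidate_conditioning_is_non_degenerate(self, rng):
        d = build_discriminator(DiscriminatorConfig(levels=3, base_filters=4),
                                seed=4)
        c = rng.standard_normal((16, 16, 16))
        x = rng.standard_normal((16, 16, 16))
        assert not np.allclose(d.forward(c, x), d.forward(c, 0.5 * x))

    def test_incompatible_shape_rejected(self, rng):
        d = build_discriminator(DiscriminatorConfig(levels=4, base_filters=4),
                                seed=5)
        with pytest.raises(ValueError, match="reducible"):
            d.forward(np.zeros((12, 16, 16)), np.zeros((12, 16, 16)))
        with pytest.raises(ValueError, match="shape"):
            d.forward(np.zeros((16, 16, 16)), np.zeros((16, 16, 32)))


class TestLosses:
    def test_l1_identical_and_unit(self):
        assert l1_loss(np.ones((4, 4, 4)), np.ones((4, 4, 4))) == 0.0
        assert l1_loss(np.ones((4, 4, 4)), np.zeros((4, 4, 4))) == 1.0

    def test_l1_matches_loop_oracle(self, rng):
        a, b = rng.random((5, 5, 5)), rng.random((5, 5, 5))
        acc = 0.0
        for i in range(5):
            for j in range(5):
                for k in range(5):
                    acc += abs(a[i, j, k] - b[i, j, k])
        assert l1_loss(a, b) == pytest.approx(acc / 125, rel=1e-12)

    def test_indifferent_discriminator_gives_two_log_two(self, rng):
        x = rng.random((8, 8, 8))
        terms = loss_discriminator(ConstD(0.5), x, x, 0.5 * x)
        assert terms.d_total == pytest.approx(2 * math.log(2), rel=1e-6)

    def test_perfect_discriminator_near_zero_loss(self, rng):
        x = rng.random((8, 8, 8))

        class PerfectD:
            def forward(self, c, cand, train=False):
                real = np.allclose(cand, x)
                return np.full((2, 2, 2), 1.0 if real else 0.0,
                               dtype=np.float32)

        terms = loss_discriminator(PerfectD(), x, x, 0.5 * x)
        assert terms.d_total == pytest.approx(0.0, abs=1e-5)

    def test_generator_identity_fake_with_indifferent_d(self, rng):
        x = rng.random((8, 8, 8))
        terms = loss_generator(ConstD(0.5), x, x, x.copy())
        assert terms.g_l1 == 0.0
        assert terms.g_total == pytest.approx(math.log(2), rel=1e-6)

    def test_lambda_zero_reduces_to_adversarial(self, rng):
        x, xf = rng.random((8, 8, 8)), rng.random((8, 8, 8))
        terms = loss_generator(ConstD(0.3), x, x, xf, lam=0.0)
        assert terms.g_total == pytest.approx(-math.log(0.3), rel=1e-6)

    def test_matches_scalar_recompute_with_real_discriminator(self, rng):
        d = build_discriminator(DiscriminatorConfig(levels=3, base_filters=4),
                                seed=6)
        c = rng.random((16, 16, 16)).astype(np.float32)
        x = rng.random((16, 16, 16)).astype(np.float32)
        xf = rng.random((16, 16, 16)).astype(np.float32)
        terms = loss_discriminator(d, c, x, xf)
        p_real = d.forward(c, x)
        p_fake = d.forward(c, xf)
        expect_real = -np.mean([math.log(v) for v in p_real.ravel()])
        expect_fake = -np.mean([math.log(1 - v) for v in p_fake.ravel()])
        assert terms.d_real == pytest.approx(expect_real, rel=1e-6)
        assert terms.d_fake == pytest.approx(expect_fake, rel=1e-6)
        gterms = loss_generator(d, c, x, xf, lam=100.0)
        expect_adv = -np.mean([math.log(v) for v in p_fake.ravel()])
        assert gterms.g_adv == pytest.approx(expect_adv, rel=1e-6)
        assert gterms.g_total == pytest.approx(
            expect_adv + 100.0 * np.mean(np.abs(x - xf)), rel=1e-6)

    def test_losses_finite_for_extreme_probabilities(self, rng):
        x = rng.random((8, 8, 8))
        for p in (0.0, 1.0):
            terms = loss_discriminator(ConstD(p), x, x, 0.5 * x)
            assert np.isfinite(terms.d_total)


class TestTrainingSignal:
    def test_one_generator_step_decreases_l1(self, rng):
        """With a dominant L1 weight, a single Adam step on one pair must
        strictly reduce the reconstruction error on that pair."""
        gcfg = GeneratorConfig(depth=3, base_filters=8, dropout_layers=0)
        g = build_generator(gcfg, seed=7)
        c = rng.random((16, 16, 16)).astype(np.float32)
        x = np.clip(c * 0.8, -1, 1).astype(np.float32)
        opt = Adam(g.layers(), lr=2e-4)
        out0 = g.forward(c, train=True)
        before = l1_loss(x, out0)
        g.zero_grad()
        g.backward(np.sign(out0 - x) / out0.size * 1e4)
        opt.step()
        after = l1_loss(x, g.forward(c, train=True))
        assert after < before

    def test_serialization_round_trip_preserves_outputs(self, rng, tmp_path):
        g = build_generator(GeneratorConfig(depth=3, base_filters=4), seed=8)
        d = build_discriminator(DiscriminatorConfig(levels=3, base_filters=4),
                                seed=9)
        x = rng.random((16, 16, 16)).astype(np.float32)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, g, d, meta={"epoch": 5})
        g2, d2, meta = load_checkpoint(path)
        assert meta["epoch"] == 5
        np.testing.assert_array_equal(g.forward(x), g2.forward(x))
        np.testing.assert_array_equal(d.forward(x, x), d2.forward(x, x))
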