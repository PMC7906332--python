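"""Generator/critic forward contracts and the two adversarial losses."""

import numpy as np
import pytest

from pfpwgan import autodiff as ad
from pfpwgan.autodiff import Tensor
from pfpwgan.model import (Discriminator, DiscriminatorConfig, Generator,
                           GeneratorConfig, binary_cross_entropy,
                           discriminator_loss, generator_loss, gradient_penalty,
                           load_checkpoint, save_checkpoint)
from pfpwgan.nn import Adam

C = 7


@pytest.fixture
def seq_cfg():
    return GeneratorConfig(n_terms=C, mode="sequence", embed_dim=8, n_filters=4,
                           kernel_size=5, pool_size=10, pool_stride=5,
                           dense_sizes=(12, 9), n_positions=30)


@pytest.fixture
def feat_cfg():
    return GeneratorConfig(n_terms=C, mode="feature", dense_sizes=(16, 12, 8),
                           feature_dim=10)


@pytest.fixture
def models(seq_cfg):
    gen = Generator(seq_cfg, np.random.default_rng(1))
    dcfg = DiscriminatorConfig(condition=seq_cfg, label_branch_size=6,
                               trunk_sizes=(10, 9, 8, 7, 6))
    disc = Discriminator(dcfg, np.random.default_rng(2))
    return gen, disc


class TestGeneratorForward:
    def test_all_padding_input_at_init_gives_half(self, seq_cfg):
        gen = Generator(seq_cfg, np.random.default_rng(0))
        out = gen.forward(np.zeros((3, 30), dtype=np.int64))
        np.testing.assert_allclose(out.data, 0.5)  # tanh(0) = 0 -> (0+1)/2

    def test_output_shape_and_range(self, seq_cfg, rng):
        gen = Generator(seq_cfg, np.random.default_rng(0))
        x = rng.integers(0, 8001, size=(5, 30))
        out = gen.forward(x).data
        assert out.shape == (5, C)
        assert (out >= 0).all() and (out <= 1).all()

    def test_feature_mode_shape_and_range(self, feat_cfg, rng):
        gen = Generator(feat_cfg, np.random.default_rng(0))
        out = gen.forward(rng.normal(size=(4, 10))).data
        assert out.shape == (4, C) and (out >= 0).all() and (out <= 1).all()

    def test_deterministic_without_rng_stochastic_with(self, seq_cfg, rng):
        gen = Generator(seq_cfg, np.random.default_rng(0))
        x = rng.integers(1, 8001, size=(4, 30))
        a = gen.forward(x).data
        b = gen.forward(x).data
        np.testing.assert_array_equal(a, b)
        drop = np.random.default_rng(3)
        s1 = gen.forward(x, rng=drop).data
        s2 = gen.forward(x, rng=drop).data
        assert not np.array_equal(s1, s2)

    def test_shape_mismatch_rejected(self, seq_cfg, rng):
        gen = Generator(seq_cfg, np.random.default_rng(0))
        with pytest.raises(ValueError):
            gen.forward(rng.integers(0, 8001, size=(2, 31)))
        with pytest.raises(ValueError):
            gen.forward(rng.normal(size=(2, 30)))  # float input in sequence mode


class TestDiscriminatorForward:
    def test_scalar_output(self, models, rng):
        gen, disc = models
        x = rng.integers(0, 8001, size=(4, 30))
        y = rng.random((4, C))
        assert disc.forward(x, y).shape == (4, 1)

    def test_zero_parameters_give_zero_score(self, models, rng):
        _, disc = models
        for p in disc.params:
            p.data = np.zeros_like(p.data)
        x = rng.integers(0, 8001, size=(3, 30))
        out = disc.forward(x, rng.random((3, C))).data
        np.testing.assert_allclose(out, 0.0)

    def test_critic_separates_real_from_shuffled_labels(self, rng):
        # 2-term feature-mode toy task: y is a deterministic function of x,
        # fake pairs shuffle y across the batch.  After a few hundred critic
        # steps the mean real score must exceed the mean fake score.
        cfg = GeneratorConfig(n_terms=2, mode="feature", dense_sizes=(8, 8, 8),
                              feature_dim=4)
        dcfg = DiscriminatorConfig(condition=cfg, label_branch_size=8,
                                   trunk_sizes=(16, 16, 8, 8, 8))
        disc = Discriminator(dcfg, np.random.default_rng(5))
        opt = Adam(disc.params, 1e-3)
        X = rng.normal(size=(64, 4))
        Y = np.stack([(X[:, 0] > 0), (X[:, 1] > 0)], axis=1).astype(float)
        for step in range(200):
            perm = rng.permutation(64)
            cond = disc.condition(X)
            d_real = ad.tmean(disc.score(cond, Y))
            d_fake = ad.tmean(disc.score(cond, Y[perm]))
            y_t = Tensor(0.5 * Y + 0.5 * Y[perm], requires_grad=True)
            pen, _ = gradient_penalty(lambda yt: disc.score(cond, yt), y_t)
            loss = ad.add(ad.add(d_fake, ad.mul(d_real, -1.0)), ad.mul(pen, 10.0))
            opt.step(ad.grad(loss, disc.params))
        cond = disc.condition(X)
        assert disc.score(cond, Y).data.mean() > disc.score(cond, Y[rng.permutation(64)]).data.mean()


class TestGeneratorLoss:
    def test_lambda1_zero_is_plain_bce(self, models, rng):
        gen, disc = models
        x = rng.integers(0, 8001, size=(6, 30))
        y = rng.integers(0, 2, size=(6, C)).astype(float)
        loss, _ = generator_loss(disc, gen, x, y, 0.0)
        p = np.clip(gen.forward(x).data, 1e-7, 1 - 1e-7)
        ref = -(y * np.log(p) + (1 - y) * np.log(1 - p)).mean()
        assert abs(loss.item() - ref) < 1e-6

    def test_half_score_single_positive_is_log_two(self):
        bce = binary_cross_entropy(np.array([[1.0]]), Tensor(np.array([[0.5]])))
        assert abs(bce.item() - np.log(2)) < 1e-12

    def test_perfect_prediction_leaves_only_wasserstein_term(self, models, rng):
        gen, disc = models

        class Perfect:
            def forward(self, x, rng=None):
                return Tensor(self.y)

        y = rng.integers(0, 2, size=(4, C)).astype(float)
        perfect = Perfect()
        perfect.y = y
        x = rng.integers(0, 8001, size=(4, 30))
        loss, aux = generator_loss(disc, perfect, x, y, 0.7)
        d = disc.forward(x, y).data.mean()
        # BCE at clipped perfect predictions is ~1e-7, not exactly 0
        assert abs(loss.item() - (aux["bce"] - 0.7 * d)) < 1e-12
        assert aux["bce"] < 1e-5

    def test_non_binary_truth_rejected(self, models, rng):
        gen, disc = models
        x = rng.integers(0, 8001, size=(2, 30))
        with pytest.raises(ValueError):
            generator_loss(disc, gen, x, np.full((2, C), 0.5), 0.0)


class TestDiscriminatorLoss:
    def test_constant_critic_and_no_penalty_gives_zero(self, models, rng):
        gen, _ = models

        class Const:
            def condition(self, x):
                return Tensor(np.zeros((len(x), 1)))

            def score(self, cond, y):
                return ad.mul(ad.tsum(ad.as_tensor(y), axis=1, keepdims=True), 0.0)

        x = rng.integers(0, 8001, size=(4, 30))
        y = rng.integers(0, 2, size=(4, C)).astype(float)
        loss, _ = discriminator_loss(Const(), gen, x, y, 0.0, rng.random(4))
        assert abs(loss.item()) < 1e-12

    def test_linear_critic_penalty_closed_form(self, models, rng):
        """D(x, y) = sum(y): gradient norm is sqrt(c), penalty lambda2*(sqrt(c)-1)^2."""
        gen, _ = models

        class Linear:
            def condition(self, x):
                return None

            def score(self, cond, y):
                return ad.tsum(ad.as_tensor(y), axis=1, keepdims=True)

        x = rng.integers(0, 8001, size=(5, 30))
        y = rng.integers(0, 2, size=(5, C)).astype(float)
        lam2 = 10.0
        loss, aux = discriminator_loss(Linear(), gen, x, y, lam2, rng.random(5))
        expected_pen = (np.sqrt(C) - 1.0) ** 2
        assert abs(aux["gradient_penalty"] - expected_pen) < 1e-6
        # wasserstein part: mean(sum(fake)) - mean(sum(real))
        fake = gen.forward(x).data.sum(axis=1).mean()
        real = y.sum(axis=1).mean()
        assert abs(loss.item() - (fake - real + lam2 * expected_pen)) < 1e-9

    def test_generator_equal_truth_collapses_interpolation(self, models, rng):
        gen, disc = models

        class Perfect:
            def __init__(self, y):
                self.y = y

            def forward(self, x, rng=None):
                return Tensor(self.y)

        y = rng.integers(0, 2, size=(4, C)).astype(float)
        x = rng.integers(0, 8001, size=(4, 30))
        loss, aux = discriminator_loss(disc, Perfect(y), x, y, 0.0, rng.random(4))
        assert abs(aux["wasserstein"]) < 1e-12
        assert abs(loss.item()) < 1e-12

    def test_unit_gradient_norm_gives_zero_penalty(self, rng):
        w = np.zeros((C, 1))
        w[0, 0] = 1.0  # ||grad|| = 1 exactly

        def score(yt):
            return ad.matmul(yt, Tensor(w))

        y_t = Tensor(rng.random((4, C)), requires_grad=True)
        pen, norms = gradient_penalty(score, y_t)
        assert abs(pen.item()) < 1e-10
        np.testing.assert_allclose(norms.data, 1.0, atol=1e-9)


class TestCheckpoint:
    def test_roundtrip(self, models, tmp_path, rng):
        gen, disc = models
        x = rng.integers(0, 8001, size=(3, 30))
        before = gen.forward(x).data
        save_checkpoint(tmp_path / "ck.npz", gen, disc, {"note": "t"})
        gen2, disc2, extra = load_checkpoint(tmp_path / "ck.npz")
        np.testing.assert_array_equal(gen2.forward(x).data, before)
        assert extra == {"note": "t"}
        assert disc2 is not None
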