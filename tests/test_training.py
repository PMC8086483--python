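"""Loss arithmetic, training-loop contracts, determinism, checkpointing."""

import numpy as np
import pytest

from nlmstain.models import DiscriminatorSpecPatchGAN, GeneratorSpecResNet, GeneratorSpecUNet
from nlmstain.phantom import PhantomParams, generate_patch_dataset
from nlmstain.training import (
    Checkpoint,
    TrainConfig,
    cycle_objective,
    discriminator_loss,
    generator_loss_pix2pix,
    make_supervised_patches,
    select_checkpoint,
    train_cyclegan,
    train_pix2pix,
)


def tiny_config(**kw):
    """16×16-patch profile so loop tests run in seconds."""
    kw.setdefault("epochs", 2)
    kw.setdefault("checkpoint_interval", kw["epochs"])
    kw.setdefault("unet_spec", GeneratorSpecUNet.reduced(scale=16, depth=4))
    kw.setdefault("resnet_spec", GeneratorSpecResNet(base_filters=(4, 8, 8), n_res_blocks=2))
    kw.setdefault("disc_spec", DiscriminatorSpecPatchGAN.reduced(scale=16))
    return TrainConfig(**kw)


@pytest.fixture(scope="module")
def tiny_pairs():
    params = PhantomParams(image_size=(128, 128), crypt_count=2, crypt_radius_range=(10, 18), seed=5)
    return make_supervised_patches(generate_patch_dataset(params, 8, patch_size=16, paired=True))


class TestDiscriminatorLoss:
    @pytest.mark.parametrize(
        "d_gen,d_tgt,raw,weighted",
        [(0.0, 1.0, 0.0, 0.0), (1.0, 0.0, 2.0, 1.0), (0.5, 0.5, 0.5, 0.25)],
    )
    def test_squared_error_form(self, d_gen, d_tgt, raw, weighted):
        r, w = discriminator_loss(d_gen, d_tgt)
        assert r == pytest.approx(raw) and w == pytest.approx(weighted)

    def test_raw_loss_bounded_by_two(self, rng):
        for _ in range(50):
            r, _ = discriminator_loss(rng.random(), rng.random())
            assert 0.0 <= r <= 2.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            discriminator_loss(1.2, 0.5)


class TestGeneratorLoss:
    def test_perfect_generator(self):
        z = np.zeros((3, 4, 4))
        loss, terms = generator_loss_pix2pix(z, z, 1.0)
        assert loss == 0.0

    def test_fooled_discriminator_contributes_unit_adversarial_term(self):
        z = np.zeros((3, 4, 4))
        loss, terms = generator_loss_pix2pix(z, z, 0.0)
        assert loss == 1.0 and terms["adv"] == 1.0

    def test_mae_weighting(self):
        a = np.zeros((3, 4, 4))
        b = np.full((3, 4, 4), 0.1)
        loss, _ = generator_loss_pix2pix(a, b, 1.0, lambda_mae=10)
        assert loss == pytest.approx(1.0)

    def test_lambda_zero_reduces_to_adversarial(self, rng):
        a, b = rng.uniform(-1, 1, (3, 4, 4)), rng.uniform(-1, 1, (3, 4, 4))
        loss, terms = generator_loss_pix2pix(a, b, 0.3, lambda_mae=0.0)
        assert loss == pytest.approx((1 - 0.3) ** 2)
        assert 0.0 <= terms["adv"] <= 1.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            generator_loss_pix2pix(np.zeros((3, 4, 4)), np.zeros((3, 8, 8)), 0.5)


class TestCycleObjective:
    def test_identity_generators_zero_cycle_terms(self, rng):
        x, y = rng.uniform(-1, 1, (1, 2, 2)), rng.uniform(-1, 1, (1, 2, 2))
        ident = lambda t: t
        terms = cycle_objective(ident, ident, None, x, y)
        assert terms["identity"] == 0.0
        assert terms["cycle_forward"] == 0.0 and terms["cycle_backward"] == 0.0

    def test_hand_computed_forward_cycle(self):
        x = np.zeros((1, 2, 2))
        y = np.zeros((1, 2, 2))
        g1 = lambda t: t + 0.1
        g2 = lambda t: t
        terms = cycle_objective(g1, g2, None, x, y)
        assert terms["cycle_forward"] == pytest.approx(0.1)

    def test_weight_ratio_1_5_10_10(self):
        # every raw term equals 1 -> breakdown combines to 1+5+10+10
        x = np.zeros((1, 2, 2))
        y = np.zeros((1, 2, 2))
        g1 = lambda t: t + 1.0
        g2 = lambda t: t
        d1 = lambda t: np.zeros((1, 1, 1))
        terms = cycle_objective(g1, g2, d1, x, y)
        assert [terms[k] for k in ("adv", "identity", "cycle_forward", "cycle_backward")] == [1, 1, 1, 1]
        assert terms["weighted_total"] == pytest.approx(26.0)

    def test_zero_weights_zero_objective(self, rng):
        x, y = rng.uniform(-1, 1, (1, 2, 2)), rng.uniform(-1, 1, (1, 2, 2))
        terms = cycle_objective(lambda t: t + 1, lambda t: t - 1, None, x, y, weights=(0, 0, 0, 0))
        assert terms["weighted_total"] == 0.0

    def test_missing_domain_patch(self):
        with pytest.raises(ValueError):
            cycle_objective(lambda t: t, lambda t: t, None, None, np.zeros((1, 2, 2)))


class TestTrainConfig:
    def test_checkpoint_interval_must_divide_epochs(self):
        with pytest.raises(ValueError):
            TrainConfig(epochs=7, checkpoint_interval=5)

    def test_checkpoint_schedule_of_published_run(self):
        cfg = TrainConfig(epochs=100, checkpoint_interval=5)
        assert cfg.epochs // cfg.checkpoint_interval == 20


class TestPix2PixLoop:
    def test_losses_finite_and_checkpoints_counted(self, tiny_pairs):
        res = train_pix2pix(tiny_pairs, tiny_config(epochs=4, checkpoint_interval=2, seed=0))
        assert len(res.checkpoints) == 2
        assert [c.epoch for c in res.checkpoints] == [2, 4]
        assert all(np.isfinite(r.g_loss) and np.isfinite(r.d_loss) for r in res.losses)
        assert all(r.d_loss >= 0 and r.g_loss >= 0 for r in res.losses)

    def test_seed_replay_is_bit_identical(self, tiny_pairs):
        r1 = train_pix2pix(tiny_pairs, tiny_config(seed=3))
        r2 = train_pix2pix(tiny_pairs, tiny_config(seed=3))
        assert [(l.d_loss, l.g_loss) for l in r1.losses] == [(l.d_loss, l.g_loss) for l in r2.losses]
        for a, b in zip(r1.generator.params(), r2.generator.params()):
            np.testing.assert_array_equal(a.data, b.data)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train_pix2pix([], tiny_config())


class TestCycleGANLoop:
    def test_losses_finite_and_terms_present(self, tiny_pairs):
        xs = [p[0] for p in tiny_pairs]
        ys = [p[1] for p in tiny_pairs]
        res = train_cyclegan(xs, ys, tiny_config(epochs=2, seed=1))
        assert {"adv", "identity", "cycle_forward", "cycle_backward"} <= set(res.losses[0].terms)
        assert all(np.isfinite(r.g_loss) for r in res.losses)
        assert len(res.checkpoints) == 1 and res.checkpoints[0].extra_state is not None

    def test_missing_domain_rejected(self, tiny_pairs):
        with pytest.raises(ValueError):
            train_cyclegan([], [p[1] for p in tiny_pairs], tiny_config())


class TestCheckpointSelection:
    def test_trained_beats_random_under_ssim(self, tiny_pairs):
        cfg = tiny_config(epochs=4, checkpoint_interval=4, seed=2)
        res = train_pix2pix(tiny_pairs, cfg)
        trained = res.checkpoints[-1]
        from nlmstain.models import UNetGenerator, init_weights

        rnd = init_weights(UNetGenerator(cfg.unet_spec), sigma=0.5, seed=99)
        random_ck = Checkpoint(epoch=1, state=rnd.state_dict(), spec=cfg.unet_spec)
        best = select_checkpoint([random_ck, trained], tiny_pairs, metric="mse")
        assert best is trained

    def test_tie_breaks_toward_later_epoch(self, tiny_pairs):
        cfg = tiny_config(seed=4)
        res = train_pix2pix(tiny_pairs, cfg)
        ck = res.checkpoints[-1]
        earlier = Checkpoint(epoch=ck.epoch - 1, state=ck.state, spec=ck.spec)
        best = select_checkpoint([ck, earlier], tiny_pairs, metric="css")
        assert best.epoch == ck.epoch

    def test_single_checkpoint_returned(self, tiny_pairs):
        cfg = tiny_config(seed=5)
        res = train_pix2pix(tiny_pairs, cfg)
        assert select_checkpoint(res.checkpoints[-1:], tiny_pairs, metric="mse") is res.checkpoints[-1]

    def test_empty_validation_rejected(self, tiny_pairs):
        res = train_pix2pix(tiny_pairs, tiny_config(seed=6))
        with pytest.raises(ValueError):
            select_checkpoint(res.checkpoints, [], metric="ssim")
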