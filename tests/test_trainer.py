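"""Alternating adversarial training loop: scope, bookkeeping, reproducibility."""

import numpy as np
import pytest

from lesiongan import nn
from lesiongan.checkpoint import load_model, save_model
from lesiongan.discriminator import DiscriminatorConfig
from lesiongan.errors import ConfigurationError, ContractError
from lesiongan.fixtures import DatasetManifest, SceneParams, generate_scene
from lesiongan.losses import dice_loss
from lesiongan.mgan import MganConfig
from lesiongan.nn import Tensor
from lesiongan.trainer import (
    TrainConfig,
    discriminator_step,
    generator_step,
    make_state,
    predict,
    train,
    validation_dice,
)


def tiny_config(**overrides) -> TrainConfig:
    base = dict(
        generator="mgan", epochs=1, batch_size=2, size=64, seed=5,
        generator_config=MganConfig(input_size=64).with_width_scale(0.125),
        discriminator_config=DiscriminatorConfig().scaled(0.125),
    )
    base.update(overrides)
    return TrainConfig(**base)


@pytest.fixture
def batch(rng):
    imgs, masks = [], []
    for seed in range(2):
        img, msk = generate_scene(SceneParams(image_size=64), seed)
        imgs.append(img.transpose(2, 0, 1))
        masks.append(msk)
    return np.stack(imgs), np.stack(masks)


def param_snapshot(model):
    return [p.data.copy() for p in model.parameters()]


def any_changed(before, model):
    return any(not np.array_equal(b, p.data)
               for b, p in zip(before, model.parameters()))


class TestStepScope:
    def test_discriminator_step_updates_only_discriminator(self, batch):
        state = make_state(tiny_config())
        g0, d0 = param_snapshot(state.generator), param_snapshot(state.discriminator)
        discriminator_step(batch, state)
        assert not any_changed(g0, state.generator)
        assert any_changed(d0, state.discriminator)

    def test_generator_step_updates_only_generator(self, batch):
        state = make_state(tiny_config())
        g0, d0 = param_snapshot(state.generator), param_snapshot(state.discriminator)
        generator_step(batch, state)
        assert any_changed(g0, state.generator)
        assert not any_changed(d0, state.discriminator)

    def test_lambda_zero_reduces_to_supervised_descent(self, batch):
        state = make_state(tiny_config(lambda_adv=0.0))
        generator_step(batch, state)
        rec = state.history[-1]
        assert rec["g_adv"] == 0.0
        assert np.isfinite(rec["g_dice"]) and np.isfinite(rec["g_smooth"])

    def test_discriminator_loss_decreases_on_frozen_batch(self, batch):
        state = make_state(tiny_config(lr_d=1e-3))
        losses = []
        for _ in range(20):
            discriminator_step(batch, state)
            rec = state.history[-1]
            losses.append(rec["d_real"] + rec["d_fake"])
        assert np.mean(losses[-5:]) < np.mean(losses[:5])


class TestTrainLoop:
    def test_step_bookkeeping(self, tiny_dataset):
        sub = DatasetManifest(root=tiny_dataset.root, records=tiny_dataset.records[:4])
        cfg = tiny_config(epochs=1, batch_size=2, val_split=0.5)
        _, _, log = train(sub, cfg)
        d_steps = [r for r in log["steps"] if r["phase"] == "D"]
        g_steps = [r for r in log["steps"] if r["phase"] == "G"]
        # 4 records, half held out -> one batch of 2 -> one alternation cycle
        assert len(d_steps) == len(g_steps) == 1

    def test_empty_manifest_rejected(self, tmp_path):
        with pytest.raises(ContractError):
            train(DatasetManifest(root=tmp_path, records=[]), tiny_config())

    def test_identical_runs_reproduce_validation_dice(self, tiny_dataset):
        cfg = tiny_config(epochs=2)
        _, _, log1 = train(tiny_dataset, cfg)
        _, _, log2 = train(tiny_dataset, cfg)
        assert log1["validation"] == log2["validation"]

    def test_overfits_single_pair_without_adversary(self):
        """With the adversarial term off, 200 steps drive dice below 0.05."""
        img, msk = generate_scene(SceneParams(image_size=64), 2)
        images = img.transpose(2, 0, 1)[None]
        masks = msk[None]
        state = make_state(tiny_config(
            lambda_adv=0.0, lr_g=1e-3, seed=0,
            generator_config=MganConfig(input_size=64).with_width_scale(0.25)))
        for _ in range(200):
            generator_step((images, masks), state)
        assert state.history[-1]["g_dice"] < 0.05


class TestCheckpointing:
    def test_round_trip_is_bit_exact(self, tmp_path, rng):
        state = make_state(tiny_config())
        path = save_model(tmp_path / "gen.npz", state.generator)
        clone = load_model(path)
        for (ka, va), (kb, vb) in zip(sorted(state.generator.state_dict().items()),
                                      sorted(clone.state_dict().items())):
            assert ka == kb
            np.testing.assert_array_equal(va, vb)
        img = rng.random((8, 3, 64, 64)).astype(np.float32)
        state.generator.eval()
        clone.eval()
        np.testing.assert_array_equal(state.generator(Tensor(img)).data,
                                      clone(Tensor(img)).data)

    def test_validation_dice_preserved_across_round_trip(self, tmp_path, tiny_dataset):
        cfg = tiny_config(epochs=1, outdir=str(tmp_path / "run"))
        gen, _, log = train(tiny_dataset, cfg)
        clone = load_model(tmp_path / "run" / "generator_final.npz")
        imgs, msks = [], []
        from lesiongan.fixtures import read_image, read_mask
        for i in range(len(tiny_dataset)):
            imgs.append(read_image(tiny_dataset.image_path(i)).transpose(2, 0, 1))
            msks.append(read_mask(tiny_dataset.mask_path(i)))
        imgs, msks = np.stack(imgs), np.stack(msks)
        assert validation_dice(gen, imgs, msks) == validation_dice(clone, imgs, msks)


class TestPredict:
    class StubGenerator(nn.Module):
        def __init__(self, prob):
            super().__init__()
            self.prob = prob

        def forward(self, x):
            b = x.data.shape[0]
            return Tensor(np.broadcast_to(self.prob[None, None], (b, 1) + self.prob.shape).copy())

    def test_high_probability_gives_all_ones(self):
        gen = self.StubGenerator(np.full((8, 8), 0.9, np.float32))
        out = predict(gen, np.zeros((8, 8, 3), np.float32))
        assert np.all(out == 1)

    def test_low_probability_gives_all_zeros(self):
        gen = self.StubGenerator(np.full((8, 8), 0.1, np.float32))
        out = predict(gen, np.zeros((8, 8, 3), np.float32))
        assert np.all(out == 0)

    def test_threshold_tie_is_foreground(self):
        prob = np.zeros((8, 8), np.float32)
        prob[0, :3] = [0.4, 0.5, 0.6]
        gen = self.StubGenerator(prob)
        out = predict(gen, np.zeros((8, 8, 3), np.float32), threshold=0.5)
        assert list(out[0, :3]) == [0, 1, 1]

    def test_invalid_threshold_rejected(self):
        gen = self.StubGenerator(np.full((8, 8), 0.9, np.float32))
        with pytest.raises(ContractError):
            predict(gen, np.zeros((8, 8, 3), np.float32), threshold=1.5)


def test_invalid_train_configs_rejected():
    with pytest.raises(ConfigurationError):
        TrainConfig(generator="unet")
    with pytest.raises(ConfigurationError):
        TrainConfig(val_split=1.5)
    with pytest.raises(ConfigurationError):
        TrainConfig(lambda_adv=-1.0)
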