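"""Alternating adversarial training of a generator against the patch discriminator.

Each batch runs a two-step min-max cycle.  The discriminator step scores the
ground-truth masks (label: real) and the generator's probability maps,
detached (label: fake), and descends their summed patch cross-entropy.  The
generator step descends the combined segmentation loss (dice + weighted
boundary smoothing) plus ``lambda_adv`` times the non-saturating adversarial
term — the cross-entropy of the discriminator's scores on the generated maps
against the *real* label — with gradients flowing through the discriminator
but only the generator's parameters updated.  Setting ``lambda_adv = 0``
degenerates to plain supervised training, which serves as the ablation of
the adversarial term.

All randomness (parameter init, data order, validation split) derives from
one seed, so a run is fully reproducible.  The best-validation-dice
generator is checkpointed and returned.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .checkpoint import save_model
from .discriminator import DiscriminatorConfig, build_discriminator
from .egan import EganConfig, build_egan
from .errors import ConfigurationError, ContractError, TrainingDivergedError
from .fixtures import DatasetManifest, read_image, read_mask, resize_pair
from .losses import adversarial_bce, dice_loss, smoothing_loss
from .mgan import MganConfig, build_mgan
from .nn import Adam, Tensor

__all__ = [
    "TrainConfig",
    "TrainingState",
    "discriminator_step",
    "generator_step",
    "train",
    "predict",
]


@dataclass
class TrainConfig:
    generator: str = "mgan"                 # "egan" | "mgan"
    epochs: int = 30
    batch_size: int = 4
    lr_g: float = 2e-4
    lr_d: float = 2e-4
    betas: tuple[float, float] = (0.5, 0.999)
    lambda_adv: float = 1.0
    smoothing_weight: float = 1.0
    smoothing_normalize: bool = True        # per-pixel mean keeps the term on dice scale
    size: int = 512                         # working resolution
    val_split: float = 0.2
    seed: int = 0
    threshold: float = 0.5
    outdir: str | None = None
    generator_config: object | None = None      # EganConfig / MganConfig override
    discriminator_config: DiscriminatorConfig | None = None

    def __post_init__(self):
        if self.generator not in ("egan", "mgan"):
            raise ConfigurationError("generator must be 'egan' or 'mgan'")
        if not (0.0 < self.val_split < 1.0):
            raise ConfigurationError("val_split must be in (0, 1)")
        if self.batch_size < 1 or self.epochs < 0:
            raise ConfigurationError("batch_size >= 1 and epochs >= 0 required")
        if self.lambda_adv < 0 or self.smoothing_weight < 0:
            raise ConfigurationError("loss weights must be nonnegative")


@dataclass
class TrainingState:
    generator: nn.Module
    discriminator: nn.Module
    opt_g: Adam
    opt_d: Adam
    config: TrainConfig
    step: int = 0
    epoch: int = 0
    history: list[dict] = field(default_factory=list)


def _build_generator(config: TrainConfig):
    if config.generator_config is not None:
        gc = config.generator_config
        return build_egan(gc) if isinstance(gc, EganConfig) else build_mgan(gc)
    if config.generator == "egan":
        return build_egan(EganConfig(input_size=config.size))
    return build_mgan(MganConfig(input_size=config.size))


def make_state(config: TrainConfig) -> TrainingState:
    """Seeded construction of models and optimizers."""
    nn.seed(config.seed)
    gen = _build_generator(config)
    disc = build_discriminator(config.discriminator_config or DiscriminatorConfig())
    return TrainingState(
        generator=gen, discriminator=disc,
        opt_g=Adam(gen.parameters(), lr=config.lr_g, betas=config.betas),
        opt_d=Adam(disc.parameters(), lr=config.lr_d, betas=config.betas),
        config=config,
    )


def _check_finite(name: str, value: float, step: int) -> None:
    if not np.isfinite(value):
        raise TrainingDivergedError(f"{name} became non-finite at step {step}")


def discriminator_step(batch: tuple[np.ndarray, np.ndarray],
                       state: TrainingState) -> TrainingState:
    """One discriminator update: real masks vs. detached generator output."""
    images, masks = batch
    x = Tensor(images)          # (B, 3, H, W)
    real = Tensor(masks[:, None].astype(np.float32))
    with_fake = state.generator(x).detach()  # no generator gradients here

    state.opt_d.zero_grad()
    d_real = state.discriminator(real)
    d_fake = state.discriminator(Tensor(with_fake.data[:, :1]))
    loss_real = adversarial_bce(d_real, is_real=True)
    loss_fake = adversarial_bce(d_fake, is_real=False)
    loss = loss_real + loss_fake
    _check_finite("discriminator loss", loss.item(), state.step)
    loss.backward()
    state.opt_d.step()
    state.history.append({
        "step": state.step, "epoch": state.epoch, "phase": "D",
        "d_real": float(loss_real.item()), "d_fake": float(loss_fake.item()),
    })
    return state


def generator_step(batch: tuple[np.ndarray, np.ndarray],
                   state: TrainingState) -> TrainingState:
    """One generator update on combined loss + weighted adversarial term."""
    images, masks = batch
    cfg = state.config
    x = Tensor(images)
    t = masks.astype(np.float32)[:, None]

    state.opt_g.zero_grad()
    state.discriminator.zero_grad()
    pred = state.generator(x)
    d = dice_loss(pred, t)
    s = smoothing_loss(pred, t, normalize=cfg.smoothing_normalize)
    loss = d + cfg.smoothing_weight * s
    adv_val = 0.0
    if cfg.lambda_adv > 0:
        adv = adversarial_bce(state.discriminator(pred), is_real=True)
        adv_val = float(adv.item())
        loss = loss + cfg.lambda_adv * adv
    _check_finite("generator loss", loss.item(), state.step)
    loss.backward()
    state.opt_g.step()                  # discriminator grads are discarded
    state.discriminator.zero_grad()
    state.history.append({
        "step": state.step, "epoch": state.epoch, "phase": "G",
        "g_dice": float(d.item()), "g_smooth": float(s.item()), "g_adv": adv_val,
    })
    state.step += 1
    return state


def _load_pairs(manifest: DatasetManifest, size: int):
    images, masks, bad = [], [], []
    for i in range(len(manifest)):
        ip, mp = manifest.image_path(i), manifest.mask_path(i)
        if not ip.exists() or not mp.exists():
            bad.append(str(ip if not ip.exists() else mp))
            continue
        img, msk = resize_pair(read_image(ip), read_mask(mp), size)
        images.append(img.transpose(2, 0, 1))
        masks.append(msk)
    if bad:
        raise IOError(f"unreadable manifest records: {bad}")
    return np.stack(images), np.stack(masks)


def validation_dice(generator: nn.Module, images: np.ndarray, masks: np.ndarray,
                    threshold: float = 0.5, batch_size: int = 8) -> float:
    """Mean per-image dice of thresholded predictions (eval mode)."""
    was_training = generator.training
    generator.eval()
    dices = []
    for i in range(0, len(images), batch_size):
        pred = generator(Tensor(images[i:i + batch_size])).data[:, 0]
        for p, m in zip(pred, masks[i:i + batch_size]):
            hard = (p >= threshold).astype(np.float64)
            dices.append(1.0 - dice_loss(hard, m.astype(np.float64)))
    if was_training:
        generator.train()
    return float(np.mean(dices))


def train(manifest: DatasetManifest, config: TrainConfig):
    """Alternating min-max training over the manifest.

    Returns ``(generator, discriminator, log)`` where the generator carries
    the best-validation-dice weights and ``log`` holds per-step loss records
    plus per-epoch validation dice.
    """
    if len(manifest) == 0:
        raise ContractError("manifest is empty")
    state = make_state(config)
    rng = np.random.default_rng(config.seed + 1)

    images, masks = _load_pairs(manifest, config.size)
    n = len(images)
    n_val = max(1, int(round(n * config.val_split))) if n > 1 else 0
    perm = rng.permutation(n)
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    if len(train_idx) == 0:
        train_idx = perm

    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    best = (-1.0, None)
    val_log: list[dict] = []

    for epoch in range(config.epochs):
        state.epoch = epoch
        order = rng.permutation(train_idx)
        state.generator.train()
        state.discriminator.train()
        for i in range(0, len(order), config.batch_size):
            idx = order[i:i + config.batch_size]
            batch = (images[idx], masks[idx])
            discriminator_step(batch, state)
            generator_step(batch, state)
        if len(val_idx):
            vd = validation_dice(state.generator, images[val_idx], masks[val_idx],
                                 threshold=config.threshold)
        else:
            vd = validation_dice(state.generator, images[train_idx], masks[train_idx],
                                 threshold=config.threshold)
        val_log.append({"epoch": epoch, "val_dice": vd})
        if vd > best[0]:
            best = (vd, copy.deepcopy(state.generator.state_dict()))
            if outdir:
                save_model(outdir / "generator_best.npz", state.generator)
        if outdir:
            with open(outdir / "log.txt", "a") as f:
                f.write(f"epoch {epoch}: val_dice={vd:.4f}\n")

    if best[1] is not None:
        state.generator.load_state_dict(best[1])
    if outdir:
        save_model(outdir / "generator_final.npz", state.generator)
        save_model(outdir / "discriminator_final.npz", state.discriminator)
        with open(outdir / "metrics.jsonl", "w") as f:
            for rec in state.history:
                f.write(json.dumps(rec) + "\n")
            for rec in val_log:
                f.write(json.dumps(rec) + "\n")
    log = {"steps": state.history, "validation": val_log,
           "best_val_dice": best[0] if best[1] is not None else None}
    return state.generator, state.discriminator, log


def predict(generator: nn.Module, image: np.ndarray,
            threshold: float = 0.5) -> np.ndarray:
    """Threshold the generator's probability map into a binary mask.

    The tie rule is >=: a probability exactly at the threshold is foreground.
    """
    if not (0.0 < threshold < 1.0):
        raise ContractError("threshold must lie in (0, 1)")
    arr = np.asarray(image, dtype=np.float32)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ContractError(f"expected an HxWx3 image, got {arr.shape}")
    was_training = generator.training
    generator.eval()
    prob = generator(Tensor(arr.transpose(2, 0, 1)[None])).data[0, 0]
    if was_training:
        generator.train()
    return (prob >= threshold).astype(np.uint8)
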