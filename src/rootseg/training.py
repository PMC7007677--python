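"""The optimization loop: per-epoch tile re-selection, augmentation, SGD
with Nesterov momentum, a step learning-rate schedule, and best-checkpoint
selection on validation F1.

Instance selection runs afresh at the start of every epoch: candidate tiles
are drawn at random locations from each training image, root-free tiles are
discarded and at most ``tile_cap`` per image are kept. Validation is the
opposite: every tile position in the non-overlapping inference grid is
evaluated, with and without roots, and the F1 is pooled over all validation
pixels at threshold 0.5. The weights of the epoch with the highest
validation F1 are retained (early stopping by checkpoint selection).

One master seed fans out into independent per-epoch, per-image and
per-augmentation streams, so runs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import dataprep, metrics
from .augment import JitterParams, color_jitter, elastic_deform, normalize_tile, sample_elastic_params
from .nn import SGDNesterov
from .synthetic import SyntheticScene
from .unet import UNet, UNetConfig, build_unet, output_side_for_input, predict_image

__all__ = ["TrainConfig", "TrainHistory", "lr_at_epoch", "train_epoch", "fit"]


@dataclass(frozen=True)
class TrainConfig:
    """Training hyper-parameters (defaults are the full-scale settings)."""

    lr0: float = 0.01
    momentum: float = 0.99
    weight_decay: float = 1e-5
    lr_factor: float = 0.3
    lr_step: int = 30
    batch_size: int = 4
    n_candidates: int = 90
    tile_cap: int = 40
    elastic_prob: float = 0.9
    ce_weight: float = 0.3
    epochs: int = 73
    seed: int = 0
    tile_in_side: int = 572
    base_channels: int = 64
    groupnorm_groups: int = 8
    use_jitter: bool = True
    use_elastic: bool = True
    jitter: JitterParams = field(default_factory=JitterParams)

    def __post_init__(self):
        if min(self.lr0, self.lr_factor) <= 0 or self.lr_step <= 0:
            raise ValueError("learning-rate settings must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        output_side_for_input(self.tile_in_side)  # raises on invalid geometry

    @property
    def tile_out_side(self) -> int:
        return output_side_for_input(self.tile_in_side)


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    train_f1: list[float] = field(default_factory=list)
    val_f1: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_f1: float = float("nan")


def lr_at_epoch(epoch: int, config: TrainConfig) -> float:
    """lr0 * lr_factor ** floor(epoch / lr_step)."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    return config.lr0 * config.lr_factor ** (epoch // config.lr_step)


def _epoch_tiles(scenes, config: TrainConfig, epoch: int):
    """Instance-select and augment tiles for one epoch; returns a list of
    (normalized input (3,H,W) float32, binary target) pairs."""
    out_side = config.tile_out_side
    tiles = []
    for i, scene in enumerate(scenes):
        ss = np.random.SeedSequence([config.seed, epoch, i])
        sel_seed, aug_entropy = ss.generate_state(2)
        pairs = dataprep.sample_training_tiles(
            scene.image,
            scene.mask,
            n_candidates=config.n_candidates,
            cap=config.tile_cap,
            seed=int(sel_seed),
            out_side=out_side,
        )
        for j, pair in enumerate(pairs):
            img = pair.input_patch
            tgt = pair.target_patch
            jit_seed, el_seed1, el_seed2 = np.random.SeedSequence(
                [int(aug_entropy), j]
            ).generate_state(3)
            if config.use_jitter:
                img = color_jitter(img, config.jitter, int(jit_seed))
            if config.use_elastic:
                params = sample_elastic_params(int(el_seed1))
                # deform the full input patch and its padded target jointly so
                # the displacement stays registered, then crop the target back
                pad = dataprep.TILE_CONTEXT // 2
                tgt_full = np.zeros(img.shape[:2], dtype=np.uint8)
                tgt_full[pad : pad + out_side, pad : pad + out_side] = tgt
                img, tgt_full = elastic_deform(
                    img, tgt_full, params, int(el_seed2), prob=config.elastic_prob
                )
                tgt = tgt_full[pad : pad + out_side, pad : pad + out_side]
            x = normalize_tile(img).transpose(2, 0, 1)
            tiles.append((x, tgt.astype(np.float32)))
    return tiles


def train_epoch(
    model: UNet, opt: SGDNesterov, scenes: list[SyntheticScene], config: TrainConfig, epoch: int
) -> tuple[float, float]:
    """One epoch of mini-batch SGD; returns (mean loss, pooled training F1).

    Raises if instance selection yields no tiles across all images.
    """
    tiles = _epoch_tiles(scenes, config, epoch)
    if not tiles:
        raise RuntimeError(
            "instance selection produced no root-containing tiles; "
            "the training scenes need more roots"
        )
    order_rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, epoch, 10**6]).generate_state(1)[0]
    )
    order = order_rng.permutation(len(tiles))
    lr = lr_at_epoch(epoch, config)
    losses = []
    pooled = metrics.ConfusionCounts(0, 0, 0, 0)
    bs = config.batch_size
    for start in range(0, len(order), bs):
        idx = order[start : start + bs]
        x = np.stack([tiles[i][0] for i in idx]).astype(np.float32)
        g = np.stack([tiles[i][1] for i in idx])[:, None]
        p = model.forward(x, train=True)
        loss, dp = metrics.batch_loss_and_grad(p, g, ce_weight=config.ce_weight)
        model.backward(dp)
        opt.step(lr)
        losses.append(loss)
        pooled = pooled + metrics.confusion_counts((p[:, 0] >= 0.5).astype(np.uint8), g[:, 0].astype(np.uint8))
    train_f1 = metrics.classification_metrics(pooled).f1
    return float(np.mean(losses)), train_f1


def _validation_f1(model: UNet, scenes, out_side: int) -> float:
    pooled = metrics.ConfusionCounts(0, 0, 0, 0)
    for scene in scenes:
        prob = predict_image(model, scene.image, tile_out_side=out_side)
        pooled = pooled + metrics.confusion_counts((prob >= 0.5).astype(np.uint8), scene.mask)
    return metrics.classification_metrics(pooled).f1


def fit(
    train_scenes: list[SyntheticScene],
    val_scenes: list[SyntheticScene],
    config: TrainConfig,
) -> tuple[UNet, TrainHistory]:
    """Train for ``config.epochs`` epochs and return the model restored to
    the weights of the epoch with the highest validation F1, plus the
    per-epoch history. Validation never influences the weights."""
    if not train_scenes or not val_scenes:
        raise ValueError("train and validation sets must be nonempty")
    model_cfg = UNetConfig(
        base_channels=config.base_channels, groupnorm_groups=config.groupnorm_groups
    )
    model = build_unet(model_cfg, seed=config.seed)
    opt = SGDNesterov(
        model.parameters(), momentum=config.momentum, weight_decay=config.weight_decay
    )
    history = TrainHistory()
    best_weights = None
    out_side = config.tile_out_side
    for epoch in range(config.epochs):
        loss, tf1 = train_epoch(model, opt, train_scenes, config, epoch)
        vf1 = _validation_f1(model, val_scenes, out_side)
        history.train_loss.append(loss)
        history.train_f1.append(tf1)
        history.val_f1.append(vf1)
        history.lr.append(lr_at_epoch(epoch, config))
        if best_weights is None or vf1 > history.best_val_f1:
            history.best_val_f1 = vf1
            history.best_epoch = epoch
            best_weights = model.get_weights()
    model.set_weights(best_weights)
    return model, history
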