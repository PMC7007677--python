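"""Scikit-learn-style estimators wrapping the two segmentation systems.

Both estimators take ``X`` as a list of (H, W, 3) uint8 images and ``y`` as
a list of matching binary masks, expose ``get_params``/``set_params`` via
``sklearn.base.BaseEstimator``, store everything learned in trailing-
underscore attributes, and score with pooled pixel F1 — so they compose
with sklearn model selection even though their samples are images rather
than feature rows.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from . import dataprep, metrics, training
from .augment import JitterParams
from .frangi import FrangiParams, OptimizerBudget, optimize_params, segment_vesselness
from .synthetic import SyntheticScene
from .unet import predict_image

__all__ = ["UNetSegmenter", "FrangiSegmenter"]


def _as_scenes(X, y):
    scenes = []
    for img, mask in zip(X, y):
        img = np.asarray(img)
        mask = (np.asarray(mask) > 0).astype(np.uint8)
        if img.shape[:2] != mask.shape:
            raise ValueError("image and mask sizes differ")
        scenes.append(SyntheticScene(image=img, mask=mask, seed=-1, config=None))
    return scenes


def _pooled_f1(preds, y) -> float:
    pooled = metrics.ConfusionCounts(0, 0, 0, 0)
    for p, g in zip(preds, y):
        pooled = pooled + metrics.confusion_counts(p, (np.asarray(g) > 0).astype(np.uint8))
    return metrics.classification_metrics(pooled).f1


class UNetSegmenter(BaseEstimator):
    """U-Net root segmenter with the full training pipeline behind ``fit``.

    Parameters mirror :class:`rootseg.training.TrainConfig`; ``n_val`` picks
    how many images go to the internal density-ranked validation split used
    for best-epoch selection (ignored when ``fit`` receives an explicit
    ``validation`` pair).

    Fitted attributes: ``model_`` (the network, at the best-epoch weights),
    ``history_`` (per-epoch loss/F1/learning rate), ``best_val_f1_``.
    """

    def __init__(
        self,
        epochs: int = 73,
        lr0: float = 0.01,
        momentum: float = 0.99,
        weight_decay: float = 1e-5,
        lr_factor: float = 0.3,
        lr_step: int = 30,
        batch_size: int = 4,
        n_candidates: int = 90,
        tile_cap: int = 40,
        elastic_prob: float = 0.9,
        ce_weight: float = 0.3,
        tile_in_side: int = 572,
        base_channels: int = 64,
        groupnorm_groups: int = 8,
        n_val: int = 9,
        seed: int = 0,
    ):
        self.epochs = epochs
        self.lr0 = lr0
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.lr_factor = lr_factor
        self.lr_step = lr_step
        self.batch_size = batch_size
        self.n_candidates = n_candidates
        self.tile_cap = tile_cap
        self.elastic_prob = elastic_prob
        self.ce_weight = ce_weight
        self.tile_in_side = tile_in_side
        self.base_channels = base_channels
        self.groupnorm_groups = groupnorm_groups
        self.n_val = n_val
        self.seed = seed

    def _config(self) -> training.TrainConfig:
        return training.TrainConfig(
            lr0=self.lr0,
            momentum=self.momentum,
            weight_decay=self.weight_decay,
            lr_factor=self.lr_factor,
            lr_step=self.lr_step,
            batch_size=self.batch_size,
            n_candidates=self.n_candidates,
            tile_cap=self.tile_cap,
            elastic_prob=self.elastic_prob,
            ce_weight=self.ce_weight,
            epochs=self.epochs,
            seed=self.seed,
            tile_in_side=self.tile_in_side,
            base_channels=self.base_channels,
            groupnorm_groups=self.groupnorm_groups,
            jitter=JitterParams(),
        )

    def fit(self, X, y, validation=None):
        """Train on images ``X`` with masks ``y``.

        ``validation``: optional ``(X_val, y_val)`` pair; otherwise ``n_val``
        images are held out by the density-ranked even-spacing rule.
        """
        scenes = _as_scenes(X, y)
        if validation is not None:
            train_scenes = scenes
            val_scenes = _as_scenes(*validation)
        else:
            counts = [(i, int(s.mask.sum())) for i, s in enumerate(scenes)]
            split = dataprep.split_train_val(counts, n_val=self.n_val)
            train_scenes = [scenes[i] for i in split.train_ids]
            val_scenes = [scenes[i] for i in split.val_ids]
        model, history = training.fit(train_scenes, val_scenes, self._config())
        self.model_ = model
        self.history_ = history
        self.best_val_f1_ = history.best_val_f1
        return self

    def predict_proba(self, X):
        """Per-pixel root probability maps, one per image."""
        out_side = self._config().tile_out_side
        return [predict_image(self.model_, np.asarray(img), tile_out_side=out_side) for img in X]

    def predict(self, X, threshold: float = 0.5):
        """Binary masks at the given probability threshold."""
        return [(p >= threshold).astype(np.uint8) for p in self.predict_proba(X)]

    def score(self, X, y) -> float:
        """Pooled pixel F1 over all images."""
        return _pooled_f1(self.predict(X), y)


class FrangiSegmenter(BaseEstimator):
    """Frangi-vesselness baseline whose parameters ``fit`` tunes by CMA-ES
    against 1 - mean(per-image F1).

    Fitted attributes: ``params_`` (best :class:`FrangiParams`),
    ``objective_`` (best 1 - mean(F1) seen during the search).
    """

    def __init__(
        self,
        budget: int = 300,
        init_params: FrangiParams | None = None,
        init_sigma: float = 0.5,
        seed: int = 0,
    ):
        self.budget = budget
        self.init_params = init_params
        self.init_sigma = init_sigma
        self.seed = seed

    def fit(self, X, y):
        images = [np.asarray(img) for img in X]
        masks = [(np.asarray(m) > 0).astype(np.uint8) for m in y]
        budget = OptimizerBudget(
            max_evaluations=self.budget,
            init_params=self.init_params or FrangiParams(),
            init_sigma=self.init_sigma,
            seed=self.seed,
        )
        self.params_, self.objective_ = optimize_params(images, masks, budget)
        return self

    def predict(self, X):
        params = getattr(self, "params_", None) or self.init_params or FrangiParams()
        return [segment_vesselness(np.asarray(img), params) for img in X]

    def score(self, X, y) -> float:
        """Pooled pixel F1 over all images."""
        return _pooled_f1(self.predict(X), y)
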