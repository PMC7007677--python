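"""Losses and evaluation metrics for binary root segmentation.

Training minimizes a Dice loss, DL = 1 - 2*sum(p*g) / (sum(p) + sum(g)),
combined with pixel-mean binary cross-entropy weighted by 0.3. Dice handles
the severe class imbalance of root images (root pixels are well under 3% of
the image) by scoring only foreground agreement; cross-entropy adds a
well-behaved per-pixel gradient.

Evaluation reports precision, recall, F1 and accuracy from pixel confusion
counts, in two aggregation modes: pooled (counts summed over all images
before computing ratios, i.e. "all images combined") and per-image
(mean and standard deviation over images, excluding images whose ground
truth has no root pixels, for which precision/recall/F1 are undefined).
For binary masks the Dice coefficient equals F1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "PerImageStats",
    "CE_EPS",
    "dice_loss",
    "cross_entropy_loss",
    "combined_loss",
    "batch_loss_and_grad",
    "confusion_counts",
    "classification_metrics",
    "aggregate_metrics",
]

#: probability clipping for finite cross-entropy
CE_EPS = 1e-7


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn, self.tn + other.tn
        )


@dataclass(frozen=True)
class MetricsReport:
    """Classification metrics; undefined ratios (zero denominator) are NaN."""

    precision: float
    recall: float
    f1: float
    accuracy: float
    prediction_mean: float
    true_mean: float


@dataclass(frozen=True)
class PerImageStats:
    """Mean/sd of per-image metrics over images that contain roots."""

    f1_mean: float
    f1_sd: float
    precision_mean: float
    precision_sd: float
    recall_mean: float
    recall_sd: float
    n_images: int


def _check_pair(p: np.ndarray, g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(p, dtype=np.float64)
    g = np.asarray(g)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    vals = np.unique(g)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("ground truth must be binary (0/1)")
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("predictions must lie in [0, 1]")
    return p, g.astype(np.float64)


def dice_loss(p: np.ndarray, g: np.ndarray) -> float:
    """1 - 2*sum(p*g)/(sum(p)+sum(g)); 0 when both are empty (perfect
    agreement should not be penalized)."""
    p, g = _check_pair(p, g)
    denom = p.sum() + g.sum()
    if denom == 0:
        return 0.0
    return float(1.0 - 2.0 * (p * g).sum() / denom)


def cross_entropy_loss(p: np.ndarray, g: np.ndarray, eps: float = CE_EPS) -> float:
    """Pixel-mean binary cross-entropy, with p clipped to [eps, 1-eps]."""
    p, g = _check_pair(p, g)
    pc = np.clip(p, eps, 1.0 - eps)
    return float(-(g * np.log(pc) + (1.0 - g) * np.log(1.0 - pc)).mean())


def combined_loss(p: np.ndarray, g: np.ndarray, ce_weight: float = 0.3) -> float:
    """Dice loss plus ``ce_weight`` times cross-entropy."""
    return dice_loss(p, g) + ce_weight * cross_entropy_loss(p, g)


def batch_loss_and_grad(
    p: np.ndarray, g: np.ndarray, ce_weight: float = 0.3
) -> tuple[float, np.ndarray]:
    """Combined loss averaged over batch items, and its gradient w.r.t. p.

    ``p``: (B, 1, H, W) probabilities; ``g``: matching binary targets.
    The Dice term is computed per item and averaged (batch-size-invariant
    gradients); cross-entropy is the pixel mean within each item.
    """
    p = np.asarray(p, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    b = p.shape[0]
    npix = p[0].size
    pc = np.clip(p, CE_EPS, 1.0 - CE_EPS)
    loss = 0.0
    grad = np.zeros_like(p)
    for i in range(b):
        pi, gi = p[i], g[i]
        denom = pi.sum() + gi.sum()
        inter = (pi * gi).sum()
        if denom > 0:
            loss += 1.0 - 2.0 * inter / denom
            grad[i] += -2.0 * (gi * denom - inter) / denom**2
        ce = -(gi * np.log(pc[i]) + (1.0 - gi) * np.log(1.0 - pc[i])).mean()
        loss += ce_weight * ce
        grad[i] += ce_weight * (-gi / pc[i] + (1.0 - gi) / (1.0 - pc[i])) / npix
    return loss / b, grad / b


def confusion_counts(pred: np.ndarray, gt: np.ndarray) -> ConfusionCounts:
    """Pixel-wise confusion tallies for two binary masks."""
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    for name, m in (("pred", pred), ("gt", gt)):
        if not np.isin(np.unique(m), (0, 1)).all():
            raise ValueError(f"{name} mask must be binary (0/1)")
    pb = pred.astype(bool)
    gb = gt.astype(bool)
    tp = int(np.count_nonzero(pb & gb))
    fp = int(np.count_nonzero(pb & ~gb))
    fn = int(np.count_nonzero(~pb & gb))
    tn = int(np.count_nonzero(~pb & ~gb))
    return ConfusionCounts(tp, fp, fn, tn)


def classification_metrics(counts: ConfusionCounts) -> MetricsReport:
    """Precision, recall, F1 (= 2PR/(P+R)), accuracy and foreground
    fractions from confusion counts; NaN where a denominator is zero."""
    n = counts.total
    if n <= 0:
        raise ValueError("no pixels evaluated")
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    precision = tp / (tp + fp) if tp + fp else math.nan
    recall = tp / (tp + fn) if tp + fn else math.nan
    # equivalent to 2PR/(P+R) where both are defined, but also defined (as 0)
    # for an empty prediction against a non-empty truth and vice versa
    f1 = 2.0 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else math.nan
    return MetricsReport(
        precision=precision,
        recall=recall,
        f1=f1,
        accuracy=(tp + tn) / n,
        prediction_mean=(tp + fp) / n,
        true_mean=(tp + fn) / n,
    )


def aggregate_metrics(
    per_image: list[tuple[np.ndarray, np.ndarray]],
) -> tuple[MetricsReport, PerImageStats]:
    """Both aggregation modes over (prediction, ground-truth) mask pairs.

    Pooled: confusion counts summed over all images, then one report.
    Per-image: mean and (population) standard deviation of precision, recall
    and F1 over only images whose ground truth contains at least one root
    pixel; with no such image the per-image statistics are NaN.
    """
    if not per_image:
        raise ValueError("need at least one (prediction, ground truth) pair")
    pooled = ConfusionCounts(0, 0, 0, 0)
    per_f1, per_p, per_r = [], [], []
    for pred, gt in per_image:
        c = confusion_counts(pred, gt)
        pooled = pooled + c
        if c.tp + c.fn > 0:  # image contains roots
            rep = classification_metrics(c)
            per_f1.append(rep.f1)
            per_p.append(rep.precision)
            per_r.append(rep.recall)
    if per_f1:
        # nanmean: an image with an empty prediction has undefined precision
        # but a well-defined (zero) F1 and recall
        stats = PerImageStats(
            f1_mean=float(np.mean(per_f1)),
            f1_sd=float(np.std(per_f1)),
            precision_mean=float(np.nanmean(per_p)) if not np.isnan(per_p).all() else math.nan,
            precision_sd=float(np.nanstd(per_p)) if not np.isnan(per_p).all() else math.nan,
            recall_mean=float(np.mean(per_r)),
            recall_sd=float(np.std(per_r)),
            n_images=len(per_f1),
        )
    else:
        stats = PerImageStats(*([math.nan] * 6), n_images=0)
    return classification_metrics(pooled), stats
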