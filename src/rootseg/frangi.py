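"""Frangi-vesselness baseline segmenter.

Roots at the soil interface are bright, thin, curvilinear structures —
similar in local geometry to blood vessels, which the Frangi filter was
designed to enhance. The baseline pipeline is: multiscale Frangi vesselness
on the luminance channel (delegated to scikit-image), a vesselness
threshold, and removal of small connected components (8-connectivity).
Its free parameters are tuned by CMA-ES minimizing 1 - mean(F1) against
annotated masks, the same objective a practitioner would hand-tune for.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from skimage.color import rgb2gray
from skimage.filters import frangi as _skimage_frangi
from skimage.morphology import remove_small_objects

from . import metrics
from .cmaes import minimize

__all__ = [
    "FrangiParams",
    "OptimizerBudget",
    "vesselness_map",
    "segment_vesselness",
    "objective",
    "optimize_params",
]


@dataclass(frozen=True)
class FrangiParams:
    """Filter and post-processing parameters.

    ``scale_min``/``scale_max`` bound the Gaussian scales (px) probed for
    ridges; ``beta`` controls sensitivity to blob-vs-ridge shape, ``c`` to
    second-order structure-ness; components smaller than
    ``min_component_px`` pixels are removed. ``detect_bright`` selects bright
    ridges on dark background (the usual polarity for roots on soil).
    """

    scale_min: float = 1.0
    scale_max: float = 5.0
    n_scales: int = 5
    beta: float = 0.5
    c: float = 0.03
    vesselness_threshold: float = 0.25
    min_component_px: int = 20
    detect_bright: bool = True

    def __post_init__(self):
        if not (0 < self.scale_min <= self.scale_max):
            raise ValueError("need 0 < scale_min <= scale_max")
        if self.n_scales < 1:
            raise ValueError("n_scales must be >= 1")
        if self.beta <= 0 or self.c <= 0:
            raise ValueError("beta and c must be > 0")
        if not (0 <= self.vesselness_threshold <= 1):
            raise ValueError("vesselness_threshold must lie in [0, 1]")
        if self.min_component_px < 0:
            raise ValueError("min_component_px must be >= 0")


@dataclass(frozen=True)
class OptimizerBudget:
    max_evaluations: int
    init_params: FrangiParams
    init_sigma: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.max_evaluations < 1:
            raise ValueError("max_evaluations must be >= 1")


def vesselness_map(image: np.ndarray, params: FrangiParams) -> np.ndarray:
    """Per-pixel maximum Frangi vesselness over scales, in [0, 1].

    The RGB image is reduced to luminance; the measure itself is
    scikit-image's 2-D Frangi filter.
    """
    image = np.asarray(image)
    gray = rgb2gray(image) if image.ndim == 3 else image.astype(np.float64) / 255.0
    sigmas = np.linspace(params.scale_min, params.scale_max, params.n_scales)
    v = _skimage_frangi(
        gray,
        sigmas=sigmas,
        beta=params.beta,
        gamma=params.c,
        black_ridges=not params.detect_bright,
    )
    return np.clip(v, 0.0, 1.0)


def _filter_components(mask: np.ndarray, min_component_px: int) -> np.ndarray:
    """Remove 8-connected components with fewer than ``min_component_px``
    pixels."""
    if min_component_px <= 1:
        return mask
    try:
        # newer skimage: max_size removes components <= its value
        return remove_small_objects(mask, max_size=min_component_px - 1, connectivity=2)
    except TypeError:  # older skimage: min_size keeps components >= its value
        return remove_small_objects(mask, min_size=min_component_px, connectivity=2)


def segment_vesselness(image: np.ndarray, params: FrangiParams) -> np.ndarray:
    """Threshold the vesselness map and drop connected components smaller
    than ``min_component_px`` pixels (8-connectivity). Returns a 0/1 mask."""
    v = vesselness_map(image, params)
    mask = _filter_components(v > params.vesselness_threshold, params.min_component_px)
    return mask.astype(np.uint8)


def objective(params: FrangiParams, images: list, masks: list) -> float:
    """1 - mean(per-image F1) of the thresholded segmentations.

    Images whose mask has no root pixels have undefined F1 and are excluded
    with a warning, consistent with per-image reporting elsewhere.
    """
    if len(images) != len(masks) or not images:
        raise ValueError("need equal, nonempty lists of images and masks")
    f1s = []
    for img, gt in zip(images, masks):
        gt = np.asarray(gt)
        if not gt.any():
            warnings.warn("excluding a root-free image from the F1 objective")
            continue
        pred = segment_vesselness(img, params)
        f1s.append(metrics.classification_metrics(metrics.confusion_counts(pred, gt)).f1)
    if not f1s:
        raise ValueError("all images were root-free; objective undefined")
    return float(1.0 - np.mean(f1s))


# -- parameter encoding for CMA-ES ----------------------------------------
# strictly positive fields on a log scale, the threshold through a logit,
# the component-size count through log1p; keeps the search space well-scaled.

def _encode(p: FrangiParams) -> np.ndarray:
    t = np.clip(p.vesselness_threshold, 1e-6, 1 - 1e-6)
    return np.array(
        [
            np.log(p.scale_min),
            np.log(p.scale_max - p.scale_min + 1e-9),
            np.log(p.beta),
            np.log(p.c),
            np.log(t / (1 - t)),
            np.log1p(p.min_component_px),
        ]
    )


def _decode(x: np.ndarray, template: FrangiParams) -> FrangiParams:
    scale_min = float(np.exp(np.clip(x[0], -3, 4)))
    span = float(np.exp(np.clip(x[1], -9, 4)))
    return replace(
        template,
        scale_min=scale_min,
        scale_max=scale_min + span,
        beta=float(np.exp(np.clip(x[2], -7, 7))),
        c=float(np.exp(np.clip(x[3], -9, 7))),
        vesselness_threshold=float(1.0 / (1.0 + np.exp(-np.clip(x[4], -30, 30)))),
        min_component_px=int(round(np.expm1(np.clip(x[5], 0, 10)))),
    )


def optimize_params(
    images: list, masks: list, budget: OptimizerBudget
) -> tuple[FrangiParams, float]:
    """CMA-ES search over the continuous Frangi parameters (scales, beta, c,
    threshold, minimum component size); ``n_scales`` and ``detect_bright``
    stay at their initial values. Returns the best-seen parameters and
    objective; deterministic given ``budget.seed``."""
    template = budget.init_params

    def fvec(x: np.ndarray) -> float:
        return objective(_decode(x, template), images, masks)

    res = minimize(
        fvec,
        _encode(template),
        sigma0=budget.init_sigma,
        max_evaluations=budget.max_evaluations,
        seed=budget.seed,
    )
    return _decode(res.x, template), res.fun
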