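"""From segmentation masks to root measurements.

Root length is estimated by topological thinning (skeletonization) of the
binary mask followed by counting the remaining pixels; the estimate is
orientation-biased (a diagonal root of the same Euclidean length yields a
different count than an axis-aligned one), which is documented rather than
corrected. Root intensity follows the manual line-intersect method: a
square grid is overlaid and the number of root crossings per metre of grid
line is counted, where one crossing is a maximal run of foreground pixels
along a grid line. The two measures are compared by Spearman rank
correlation and the coefficient of determination of a least-squares linear
fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from skimage.morphology import skeletonize

__all__ = [
    "GridSpec",
    "CorrelationReport",
    "STUDY_GRID_SPACINGS_MM",
    "NATIVE_PX_PER_MM",
    "skeleton_length_px",
    "grid_intersect_intensity",
    "max_normalize",
    "correlate",
]

#: grid square sizes used in the manual counting campaign
STUDY_GRID_SPACINGS_MM = (10, 20, 40, 80)
#: native photograph scale: 3991 px across ~300 mm of rhizotron surface
NATIVE_PX_PER_MM = 3991 / 300


@dataclass(frozen=True)
class GridSpec:
    spacing_mm: float = 10.0
    px_per_mm: float = NATIVE_PX_PER_MM

    def __post_init__(self):
        if self.spacing_mm <= 0 or self.px_per_mm <= 0:
            raise ValueError("spacing_mm and px_per_mm must be positive")

    @property
    def spacing_px(self) -> float:
        return self.spacing_mm * self.px_per_mm


@dataclass(frozen=True)
class CorrelationReport:
    spearman_rho: float
    p_value: float
    r_squared: float
    n: int


def skeleton_length_px(mask: np.ndarray) -> int:
    """Foreground pixel count after thinning the mask to a 1-px skeleton."""
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        return 0
    return int(skeletonize(mask).sum())


def _runs(line: np.ndarray) -> int:
    """Number of maximal foreground runs in a 1-D binary array."""
    padded = np.concatenate([[0], line.astype(np.int8)])
    return int(np.count_nonzero(np.diff(padded) == 1))


def grid_intersect_intensity(mask: np.ndarray, grid: GridSpec) -> float:
    """Root intersections per metre of grid line.

    Grid lines run in both orientations at ``spacing_px`` intervals with the
    origin fixed at the image corner (0, 0); each maximal foreground run
    along a line counts as one intersection, so a root thicker than one
    pixel crossing a line counts once.
    """
    mask = np.asarray(mask).astype(bool)
    h, w = mask.shape
    sp = grid.spacing_px
    if sp < 1:
        raise ValueError(f"grid spacing {sp:.2f} px is finer than a pixel")
    if sp > max(h, w):
        raise ValueError(
            f"grid spacing {sp:.0f} px is coarser than the {w}x{h} image"
        )
    rows = np.unique(np.round(np.arange(0, h, sp)).astype(int))
    cols = np.unique(np.round(np.arange(0, w, sp)).astype(int))
    rows = rows[rows < h]
    cols = cols[cols < w]
    crossings = sum(_runs(mask[r, :]) for r in rows) + sum(_runs(mask[:, c]) for c in cols)
    px_per_m = grid.px_per_mm * 1000.0
    total_line_m = len(rows) * w / px_per_m + len(cols) * h / px_per_m
    return crossings / total_line_m


def max_normalize(series) -> np.ndarray:
    """Divide a non-negative series by its maximum (so the maximum maps to 1)."""
    arr = np.asarray(series, dtype=np.float64)
    m = arr.max() if arr.size else 0.0
    if m <= 0:
        raise ValueError("cannot max-normalize an all-zero (or empty) series")
    return arr / m


def correlate(x, y) -> CorrelationReport:
    """Spearman rank correlation (with p-value) and the r^2 of the
    least-squares linear fit of y on x, on untransformed values."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    rho, p = stats.spearmanr(x, y)
    fit = stats.linregress(x, y)
    return CorrelationReport(
        spearman_rho=float(rho), p_value=float(p), r_squared=float(fit.rvalue**2), n=int(x.size)
    )
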