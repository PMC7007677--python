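"""Seeded data augmentation: color jitter, elastic grid deformation, and
input normalization.

The elastic deformation uses a single smoothed random displacement field
applied identically to the image (bilinear resampling) and its mask
(nearest-neighbour, so the mask stays binary). Its two physical parameters
are jointly interpolated from one uniform draw gamma in [0, 1): the
elasticity sigma runs over [15, 60] px and the intensity alpha over
[200, 2500] px, because a large intensity only looks realistic at a large
elasticity; alpha is further scaled by a uniform factor in [0.4, 1) so
milder deformations also occur.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

__all__ = [
    "ElasticParams",
    "JitterParams",
    "SIGMA_RANGE",
    "ALPHA_RANGE",
    "ALPHA_SCALE_RANGE",
    "sample_elastic_params",
    "elastic_deform",
    "color_jitter",
    "normalize_tile",
]

SIGMA_RANGE = (15.0, 60.0)
ALPHA_RANGE = (200.0, 2500.0)
ALPHA_SCALE_RANGE = (0.4, 1.0)


@dataclass(frozen=True)
class ElasticParams:
    """Elastic deformation parameters tied together by one interpolation
    coefficient: sigma = 15 + gamma*(60-15), alpha = scale*(200 + gamma*(2500-200))."""

    gamma: float
    scale: float = 1.0

    @property
    def sigma(self) -> float:
        lo, hi = SIGMA_RANGE
        return lo + self.gamma * (hi - lo)

    @property
    def alpha(self) -> float:
        lo, hi = ALPHA_RANGE
        return self.scale * (lo + self.gamma * (hi - lo))


@dataclass(frozen=True)
class JitterParams:
    """Maximum jitter magnitudes; a magnitude m means a multiplicative
    factor drawn from [1-m, 1+m] (hue: an additive shift in [-m, m] of the
    hue circle)."""

    brightness: float = 0.3
    contrast: float = 0.3
    saturation: float = 0.2
    hue: float = 0.001

    def __post_init__(self):
        for name in ("brightness", "contrast", "saturation", "hue"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} magnitude must be >= 0")


def sample_elastic_params(seed: int) -> ElasticParams:
    """Draw gamma ~ U[0, 1) and the alpha scale ~ U[0.4, 1)."""
    rng = np.random.default_rng(seed)
    gamma = rng.uniform(0.0, 1.0)
    scale = rng.uniform(*ALPHA_SCALE_RANGE)
    return ElasticParams(gamma=gamma, scale=scale)


def _displacement_field(shape, sigma, alpha, rng):
    dr = gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect") * alpha
    dc = gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect") * alpha
    return dr, dc


def elastic_deform(
    image: np.ndarray,
    mask: np.ndarray | None,
    params: ElasticParams,
    seed: int,
    prob: float = 0.9,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Apply one elastic deformation jointly to an image and its mask.

    Applied with probability ``prob`` per call (identity otherwise); the
    probability gate, the displacement field and everything else derive from
    ``seed``, so the same (params, seed) always yields the same output.
    Out-of-domain samples are filled by reflection, consistent with the
    mirror padding used elsewhere.
    """
    image = np.asarray(image)
    if mask is not None:
        mask = np.asarray(mask)
        if mask.shape[:2] != image.shape[:2]:
            raise ValueError(
                f"image {image.shape[:2]} and mask {mask.shape[:2]} sizes differ"
            )
    rng = np.random.default_rng(seed)
    if rng.uniform() >= prob or params.alpha == 0:
        return image, mask
    shape = image.shape[:2]
    dr, dc = _displacement_field(shape, params.sigma, params.alpha, rng)
    rr, cc = np.meshgrid(
        np.arange(shape[0], dtype=np.float64),
        np.arange(shape[1], dtype=np.float64),
        indexing="ij",
    )
    coords = [rr + dr, cc + dc]
    if image.ndim == 3:
        out = np.stack(
            [
                map_coordinates(image[..., ch].astype(np.float64), coords, order=1, mode="reflect")
                for ch in range(image.shape[2])
            ],
            axis=-1,
        )
    else:
        out = map_coordinates(image.astype(np.float64), coords, order=1, mode="reflect")
    if np.issubdtype(image.dtype, np.integer):
        out = np.clip(np.rint(out), 0, 255).astype(image.dtype)
    else:
        out = out.astype(image.dtype)
    out_mask = None
    if mask is not None:
        out_mask = map_coordinates(mask, coords, order=0, mode="reflect").astype(mask.dtype)
    return out, out_mask


def deformation_field(params: ElasticParams, seed: int, shape: tuple[int, int], prob: float = 0.9):
    """The displacement field :func:`elastic_deform` would use for this
    (params, seed, shape) — zero if the probability gate declines. Exposed so
    the image/mask joint-deformation property can be verified directly."""
    rng = np.random.default_rng(seed)
    if rng.uniform() >= prob or params.alpha == 0:
        z = np.zeros(shape)
        return z, z.copy()
    return _displacement_field(shape, params.sigma, params.alpha, rng)


def color_jitter(image: np.ndarray, params: JitterParams, seed: int) -> np.ndarray:
    """Randomly perturb brightness, contrast, saturation and hue (in that
    fixed order); output clipped to [0, 255]. A paired mask is never touched.
    """
    from skimage.color import hsv2rgb, rgb2hsv

    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("color_jitter expects an (H, W, 3) RGB image")
    rng = np.random.default_rng(seed)
    fb = rng.uniform(1 - params.brightness, 1 + params.brightness)
    fc = rng.uniform(1 - params.contrast, 1 + params.contrast)
    fs = rng.uniform(1 - params.saturation, 1 + params.saturation)
    dh = rng.uniform(-params.hue, params.hue)

    x = image.astype(np.float64)
    x = x * fb
    gray = x @ np.array([0.299, 0.587, 0.114])
    x = fc * x + (1 - fc) * gray.mean()
    x = fs * x + (1 - fs) * gray[..., None]
    if dh != 0.0:
        hsv = rgb2hsv(np.clip(x, 0, 255) / 255.0)
        hsv[..., 0] = (hsv[..., 0] + dh) % 1.0
        x = hsv2rgb(hsv) * 255.0
    x = np.clip(x, 0, 255)
    if np.issubdtype(image.dtype, np.integer):
        return np.rint(x).astype(image.dtype)
    return x.astype(image.dtype)


def normalize_tile(image: np.ndarray) -> np.ndarray:
    """Map 8-bit intensities v in [0, 255] to v/255 - 0.5 (zero-centered
    inputs speed up gradient-descent convergence)."""
    arr = np.asarray(image, dtype=np.float32)
    if arr.size and (arr.min() < 0 or arr.max() > 255):
        raise ValueError("normalize_tile expects values in [0, 255]")
    return arr / 255.0 - 0.5
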