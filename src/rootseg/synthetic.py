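"""Seeded synthetic rhizotron scenes: soil-textured backgrounds, bright
curvilinear root tubes with exact ground-truth masks, and optional scratch
artifacts.

The generator emulates the statistics that matter for testing a root
segmenter rather than soil photorealism: spatially correlated background
texture, thin bright tubular foreground structures of variable width and
length whose pixel fraction is controlled to a configurable band (the
annotation statistics of real rhizotron photographs put root pixels between
0 and 2.8% of the image), plus occasional bright scratch-like line
artifacts that produce plausible false positives. Roots are drawn as
smoothed random-walk polylines with per-segment width jitter - branch-free
tubes, adequate for vesselness and skeleton-based measurements.

Every output is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "SceneConfig",
    "SyntheticScene",
    "GenerationError",
    "make_soil_texture",
    "make_root_scene",
    "add_scratches",
    "make_dataset",
]

#: redraw attempts before giving up on the target density band
RETRY_BUDGET = 50


class GenerationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SceneConfig:
    """Scene parameters.

    ``contrast`` is the root-vs-soil mean intensity offset (8-bit units);
    each root additionally draws a contrast multiplier from [0.5, 1.3] and a
    pale channel weighting, so some roots are faint and roots are whiter
    than the brown soil — the two properties that make real root detection
    harder than luminance thresholding;
    ``curvature`` scales the random heading change per step of the root walk
    (0 = straight tubes); ``target_fraction_band`` bounds the root-pixel
    fraction of the mask, mirroring the 0-2.8% annotation range observed on
    real images. ``dark_roots`` inverts polarity (roots darker than soil).
    """

    height: int = 200
    width: int = 200
    n_roots: int = 2
    width_range: tuple[int, int] = (2, 5)
    contrast: float = 50.0
    curvature: float = 1.0
    noise_sd: float = 6.0
    target_fraction_band: tuple[float, float] = (0.002, 0.028)
    dark_roots: bool = False

    def __post_init__(self):
        if self.height < 1 or self.width < 1:
            raise ValueError("scene dimensions must be positive")
        if self.n_roots < 0:
            raise ValueError("n_roots must be >= 0")
        if not (1 <= self.width_range[0] <= self.width_range[1]):
            raise ValueError("width_range must satisfy 1 <= min <= max")
        if not (0 <= self.contrast <= 255):
            raise ValueError("contrast must lie in [0, 255]")
        if self.curvature < 0 or self.noise_sd < 0:
            raise ValueError("curvature and noise_sd must be >= 0")
        lo, hi = self.target_fraction_band
        if not (0 <= lo <= hi <= 0.05):
            raise ValueError("target_fraction_band must satisfy 0 <= lo <= hi <= 0.05")


@dataclass(frozen=True)
class SyntheticScene:
    image: np.ndarray  # (H, W, 3) uint8
    mask: np.ndarray  # (H, W) uint8, strictly 0/1
    seed: int
    config: SceneConfig


def make_soil_texture(height: int, width: int, seed: int) -> np.ndarray:
    """A spatially correlated soil-like background, (H, W, 3) uint8.

    Two low-pass-filtered noise fields (coarse clods + fine grain) around a
    mid-dark brownish mean; fully determined by ``seed``.
    """
    if height < 1 or width < 1:
        raise ValueError("dimensions must be positive")
    rng = np.random.default_rng(seed)
    coarse = gaussian_filter(rng.standard_normal((height, width)), 8, mode="reflect")
    fine = gaussian_filter(rng.standard_normal((height, width)), 1.5, mode="reflect")
    coarse /= max(coarse.std(), 1e-9)
    fine /= max(fine.std(), 1e-9)
    lum = 90.0 + 14.0 * coarse + 8.0 * fine
    tint = np.array([1.10, 1.0, 0.85])  # slight brown cast
    img = lum[..., None] * tint[None, None, :]
    img += rng.normal(0.0, 2.0, size=img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


#: channel weighting of the root brightening: roots are pale/whitish, so the
#: blue channel (which brown soil lacks) gains the most
ROOT_COLOR_WEIGHT = np.array([0.95, 1.0, 1.2])
#: per-root contrast multiplier range ("variable contrast": some roots faint)
ROOT_CONTRAST_FACTOR_RANGE = (0.5, 1.3)


def _draw_root(mask: np.ndarray, config: SceneConfig, rng: np.random.Generator) -> None:
    """Rasterize one random-walk tube into ``mask`` in place."""
    h, w = mask.shape
    wmin, wmax = config.width_range
    # start on a random border pixel, heading inward
    side = rng.integers(4)
    if side == 0:
        r, c, heading = 0.0, rng.uniform(0, w), np.pi / 2
    elif side == 1:
        r, c, heading = float(h - 1), rng.uniform(0, w), -np.pi / 2
    elif side == 2:
        r, c, heading = rng.uniform(0, h), 0.0, 0.0
    else:
        r, c, heading = rng.uniform(0, h), float(w - 1), np.pi
    heading += rng.uniform(-0.5, 0.5)
    radius = rng.uniform(wmin, wmax) / 2.0
    max_steps = int(2.5 * (h + w))
    step = 1.0
    for _ in range(max_steps):
        heading += config.curvature * rng.normal(0.0, 0.15)
        radius = np.clip(radius + rng.normal(0.0, 0.08), wmin / 2.0, wmax / 2.0)
        r += step * np.sin(heading)
        c += step * np.cos(heading)
        if not (0 <= r < h and 0 <= c < w):
            break
        ir, ic = int(round(r)), int(round(c))
        rad = int(np.ceil(radius))
        r0, r1 = max(ir - rad, 0), min(ir + rad + 1, h)
        c0, c1 = max(ic - rad, 0), min(ic + rad + 1, w)
        yy, xx = np.mgrid[r0:r1, c0:c1]
        mask[r0:r1, c0:c1] |= ((yy - r) ** 2 + (xx - c) ** 2 <= radius**2).astype(np.uint8)


def make_root_scene(config: SceneConfig, seed: int) -> SyntheticScene:
    """Render one scene: soil texture, then root tubes brightened (or
    darkened) by ``contrast`` strictly inside the mask, then pixel noise.

    The mask is redrawn (fresh sub-seed) until its root-pixel fraction falls
    inside ``target_fraction_band``; after ``RETRY_BUDGET`` failures a
    :class:`GenerationError` naming the band is raised. With ``n_roots = 0``
    an all-background mask is accepted as is.
    """
    h, w = config.height, config.width
    ss = np.random.SeedSequence([int(seed), 2**16])
    soil_seed, draw_entropy, noise_entropy = ss.generate_state(3)
    soil = make_soil_texture(h, w, int(soil_seed)).astype(np.float64)

    lo, hi = config.target_fraction_band
    mask = np.zeros((h, w), dtype=np.uint8)
    root_masks: list[tuple[np.ndarray, float]] = []
    if config.n_roots > 0:
        ok = False
        for attempt in range(RETRY_BUDGET):
            mask[:] = 0
            root_masks = []
            rng = np.random.default_rng([int(draw_entropy), attempt])
            for _ in range(config.n_roots):
                rm = np.zeros((h, w), dtype=np.uint8)
                _draw_root(rm, config, rng)
                factor = rng.uniform(*ROOT_CONTRAST_FACTOR_RANGE)
                root_masks.append((rm, factor))
                mask |= rm
            frac = mask.mean()
            if lo <= frac <= hi:
                ok = True
                break
        if not ok:
            raise GenerationError(
                f"could not reach root-pixel fraction band [{lo}, {hi}] with "
                f"n_roots={config.n_roots}, width_range={config.width_range} "
                f"after {RETRY_BUDGET} attempts"
            )

    rng_noise = np.random.default_rng(int(noise_entropy))
    img = soil.copy()
    sign = -1.0 if config.dark_roots else 1.0
    offset = np.zeros((h, w), dtype=np.float64)
    for rm, factor in root_masks:
        np.maximum(offset, rm * (config.contrast * factor), out=offset)
    img += sign * offset[..., None] * ROOT_COLOR_WEIGHT[None, None, :]
    if config.noise_sd > 0:
        img += rng_noise.normal(0.0, config.noise_sd, size=img.shape)
    image = np.clip(img, 0, 255).astype(np.uint8)
    return SyntheticScene(image=image, mask=mask, seed=int(seed), config=config)


def add_scratches(image: np.ndarray, n_scratches: int, seed: int) -> np.ndarray:
    """Overlay thin bright line artifacts (acrylic-glass scratches) on a copy
    of the image; a paired ground-truth mask is by contract unchanged since
    scratches are not roots."""
    if n_scratches < 0:
        raise ValueError("n_scratches must be >= 0")
    image = np.asarray(image)
    out = image.copy()
    if n_scratches == 0:
        return out
    from skimage.draw import line as draw_line

    h, w = image.shape[:2]
    rng = np.random.default_rng(seed)
    for _ in range(n_scratches):
        r0, r1 = rng.integers(0, h, 2)
        c0, c1 = rng.integers(0, w, 2)
        rr, cc = draw_line(int(r0), int(c0), int(r1), int(c1))
        boost = rng.uniform(50, 90)
        vals = out[rr, cc].astype(np.float64) + boost
        out[rr, cc] = np.clip(vals, 0, 255).astype(out.dtype)
    return out


def make_dataset(n_images: int, config: SceneConfig, seed: int) -> list[SyntheticScene]:
    """Generate ``n_images`` scenes with distinct derived seeds.

    To spread root-pixel fractions across the band (so density-ranked
    splitting is exercised), scene i uses 1 + (i mod n_roots) roots when
    ``config.n_roots`` > 0; the per-scene config is recorded on each scene.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    child_seeds = np.random.SeedSequence(int(seed)).generate_state(n_images)
    scenes = []
    for i in range(n_images):
        cfg_i = config
        if config.n_roots > 0:
            cfg_i = replace(config, n_roots=1 + (i % config.n_roots))
        scenes.append(make_root_scene(cfg_i, int(child_seeds[i])))
    return scenes
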