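"""Image preparation: analysis-region cropping, mirror padding, tile
extraction and stitching, per-epoch instance selection, and the ranked
train/validation split.

Geometry convention: coordinates are 0-based (row, col) with the origin at
the top-left. A training/inference tile pairs a large input patch with the
segmentation target for its center region; the input side always exceeds
the output side by 184 pixels (92 of context per side), matching the
valid-convolution network geometry (572 in, 388 out at native tile size).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TilePair",
    "DataSplit",
    "StitchError",
    "ANALYSIS_WIDTH",
    "ANALYSIS_HEIGHT",
    "TILE_CONTEXT",
    "crop_to_analysis_region",
    "mirror_pad",
    "sample_training_tiles",
    "inference_tiles",
    "stitch_predictions",
    "split_train_val",
    "read_image",
    "read_mask",
    "write_mask",
]

#: analysis-region size at the native photograph scale (width x height)
ANALYSIS_WIDTH = 3991
ANALYSIS_HEIGHT = 1842
#: input side minus output side for every tile
TILE_CONTEXT = 184


class StitchError(RuntimeError):
    pass


@dataclass
class TilePair:
    """An input patch, the target for its centered output region, and the
    output region's top-left corner in unpadded image coordinates."""

    input_patch: np.ndarray
    target_patch: np.ndarray | None
    origin: tuple[int, int]

    def __post_init__(self):
        if self.target_patch is not None:
            din = self.input_patch.shape[0] - self.target_patch.shape[0]
            dw = self.input_patch.shape[1] - self.target_patch.shape[1]
            if din != TILE_CONTEXT or dw != TILE_CONTEXT:
                raise ValueError(
                    f"input minus output side must be {TILE_CONTEXT}, got {din}x{dw}"
                )


@dataclass
class DataSplit:
    train_ids: list = field(default_factory=list)
    val_ids: list = field(default_factory=list)
    test_ids: list = field(default_factory=list)


def crop_to_analysis_region(
    image: np.ndarray, width: int = ANALYSIS_WIDTH, height: int = ANALYSIS_HEIGHT
) -> np.ndarray:
    """Crop a photograph to the analysis region compared against manual counts.

    Surplus columns are removed from the right edge only (where adjacent
    photographs overlap); surplus rows are split evenly between top and
    bottom (where the metal frame intrudes). The native 4608x2592 photograph
    becomes 3991x1842 (375 rows off each of top and bottom).
    """
    h, w = image.shape[0], image.shape[1]
    if h < height or w < width:
        raise ValueError(f"image {w}x{h} smaller than analysis region {width}x{height}")
    top = (h - height) // 2
    return image[top : top + height, :width]


def mirror_pad(image: np.ndarray, margin: int) -> np.ndarray:
    """Reflect the image at its borders without repeating the edge pixel.

    A 1-D row [1, 2, 3] padded by 2 becomes [3, 2, 1, 2, 3, 2, 1]. Works on
    2-D masks and (H, W, C) images; only spatial axes are padded.
    """
    if margin < 0:
        raise ValueError("margin must be >= 0")
    if margin == 0:
        return image
    image = np.asarray(image)
    if image.ndim == 1:
        if margin >= image.shape[0]:
            raise ValueError("margin too large for reflection")
        return np.pad(image, margin, mode="reflect")
    if margin >= min(image.shape[0], image.shape[1]):
        raise ValueError(
            f"margin {margin} too large for {image.shape[1]}x{image.shape[0]} image"
        )
    pad = [(margin, margin), (margin, margin)] + [(0, 0)] * (image.ndim - 2)
    return np.pad(image, pad, mode="reflect")


def sample_training_tiles(
    image: np.ndarray,
    mask: np.ndarray,
    n_candidates: int = 90,
    cap: int = 40,
    seed: int = 0,
    out_side: int = 388,
) -> list[TilePair]:
    """Per-epoch instance selection for one training image.

    ``n_candidates`` output-region origins are drawn uniformly with
    replacement over all valid positions; candidates whose target patch
    contains no root pixel are discarded (only the output region contributes
    to the loss), and the first ``cap`` survivors in draw order are kept, so
    root-rich images are still limited to ``cap`` tiles. The image is
    mirror-padded internally so every origin has full context.
    """
    mask = np.asarray(mask)
    h, w = mask.shape
    if image.shape[:2] != (h, w):
        raise ValueError("image and mask sizes differ")
    if h < out_side or w < out_side:
        raise ValueError(f"image {w}x{h} smaller than tile output region {out_side}")
    margin = TILE_CONTEXT // 2
    padded = mirror_pad(image, margin)
    rng = np.random.default_rng(seed)
    rows = rng.integers(0, h - out_side + 1, size=n_candidates)
    cols = rng.integers(0, w - out_side + 1, size=n_candidates)
    tiles: list[TilePair] = []
    in_side = out_side + TILE_CONTEXT
    for r, c in zip(rows, cols):
        target = mask[r : r + out_side, c : c + out_side]
        if not target.any():
            continue
        tiles.append(
            TilePair(
                input_patch=padded[r : r + in_side, c : c + in_side],
                target_patch=target,
                origin=(int(r), int(c)),
            )
        )
        if len(tiles) == cap:
            break
    return tiles


def inference_tiles(padded_image: np.ndarray, out_side: int = 388) -> list[TilePair]:
    """Tile a mirror-padded image so the output regions cover every pixel.

    ``padded_image`` must already carry the 92-pixel context margin on each
    side. Output regions form a non-overlapping grid except at the far edges,
    where the last row/column of tiles is shifted inward so the union covers
    the image exactly; on overlapped pixels the stitcher keeps the
    later-written tile.
    """
    margin = TILE_CONTEXT // 2
    ph, pw = padded_image.shape[0], padded_image.shape[1]
    h, w = ph - TILE_CONTEXT, pw - TILE_CONTEXT
    if h < out_side or w < out_side:
        raise ValueError(
            f"padded image covers {w}x{h}, smaller than one {out_side}-pixel output region"
        )

    def starts(extent: int) -> list[int]:
        s = list(range(0, extent - out_side + 1, out_side))
        if s[-1] + out_side < extent:
            s.append(extent - out_side)
        return s

    in_side = out_side + TILE_CONTEXT
    tiles = []
    for r in starts(h):
        for c in starts(w):
            tiles.append(
                TilePair(
                    input_patch=padded_image[r : r + in_side, c : c + in_side],
                    target_patch=None,
                    origin=(r, c),
                )
            )
    return tiles


def stitch_predictions(
    tiles: list[tuple[tuple[int, int], np.ndarray]], height: int, width: int
) -> np.ndarray:
    """Assemble per-tile maps into a full-image map.

    Each element is ``(origin, map)``. Later tiles overwrite earlier ones on
    overlap; an uncovered pixel raises :class:`StitchError` naming its
    coordinate.
    """
    canvas = np.full((height, width), np.nan, dtype=np.float64)
    for origin, tile in tiles:
        r, c = origin
        th, tw = tile.shape
        if r < 0 or c < 0 or r + th > height or c + tw > width:
            raise StitchError(f"tile at {origin} with shape {tile.shape} exceeds canvas")
        canvas[r : r + th, c : c + tw] = tile
    holes = np.argwhere(np.isnan(canvas))
    if holes.size:
        r, c = holes[0]
        raise StitchError(f"pixel ({r}, {c}) not covered by any tile")
    return canvas


def split_train_val(
    root_pixel_counts: list[tuple], n_val: int = 9
) -> DataSplit:
    """Rank images by annotated root-pixel count and pick ``n_val`` evenly
    spaced ranks for validation, so both subsets span the full range of root
    densities.

    Validation ranks are round(k * (N-1) / (n_val-1)) for k = 0..n_val-1
    (ties in count broken by id; duplicate ranks shifted to the nearest
    unused rank). ``n_val = 1`` selects the median-ranked image.
    """
    n = len(root_pixel_counts)
    if n_val > n:
        raise ValueError(f"n_val ({n_val}) exceeds number of images ({n})")
    ranked = sorted(root_pixel_counts, key=lambda t: (t[1], t[0]))
    ids = [t[0] for t in ranked]
    if n_val == 0:
        return DataSplit(train_ids=list(ids), val_ids=[], test_ids=[])
    if n_val == 1:
        targets = [round((n - 1) / 2)]
    else:
        targets = [round(k * (n - 1) / (n_val - 1)) for k in range(n_val)]
    taken: set[int] = set()
    for t in targets:
        if t not in taken:
            taken.add(t)
            continue
        for off in range(1, n):
            for cand in (t + off, t - off):
                if 0 <= cand < n and cand not in taken:
                    taken.add(cand)
                    break
            else:
                continue
            break
    val_ids = [ids[i] for i in sorted(taken)]
    train_ids = [ids[i] for i in range(n) if i not in taken]
    return DataSplit(train_ids=train_ids, val_ids=val_ids, test_ids=[])


# -- file IO ---------------------------------------------------------------

def read_image(path) -> np.ndarray:
    """Read an RGB photograph as (H, W, 3) uint8."""
    import imageio.v3 as iio

    arr = iio.imread(path)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[2] == 4:
        arr = arr[:, :, :3]
    return arr.astype(np.uint8)


def read_mask(path) -> np.ndarray:
    """Read an annotation mask; any nonzero pixel counts as root."""
    import imageio.v3 as iio

    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr.max(axis=2)
    return (arr > 0).astype(np.uint8)


def write_mask(path, mask: np.ndarray) -> None:
    """Write a binary mask as a 0/255 single-channel PNG."""
    import imageio.v3 as iio

    iio.imwrite(path, (np.asarray(mask) > 0).astype(np.uint8) * 255)
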