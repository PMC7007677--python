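"""U-Net encoder-decoder for root/soil segmentation.

The topology follows the original U-Net: five resolution levels, two valid
(unpadded) 3x3 convolutions per level, 2x2 max-pooling on the way down,
learned 2x2 up-convolutions with center-cropped skip connections on the way
up, and a final 1x1 convolution (23 convolutional layers in total at full
depth). Differences from the original that this package adopts deliberately:
the input layer takes RGB, every ReLU is followed by group normalization,
there is no dropout, and the single output channel is squashed through a
sigmoid so the network emits a per-pixel root probability.

Because every convolution is unpadded, the output is smaller than the input
by a fixed margin of 184 pixels (92 per side): a 572x572 tile yields a
388x388 probability map. ``output_side_for_input`` computes this arithmetic
symbolically and rejects geometrically invalid tile sizes (any side that
would be odd before a pooling step).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import dataprep
from .augment import normalize_tile
from .nn import ConvValid, GroupNorm, MaxPool2, ReLU, UpConv2x2

__all__ = [
    "UNetConfig",
    "UNet",
    "build_unet",
    "output_side_for_input",
    "valid_input_side",
    "CONTEXT_MARGIN",
    "save_model",
    "load_model",
    "predict_tile",
    "predict_image",
]

#: input side minus output side, fixed by the valid-convolution topology
CONTEXT_MARGIN = 184


@dataclass(frozen=True)
class UNetConfig:
    """Architecture hyper-parameters.

    ``base_channels`` is 64 in the original network; it can be reduced for
    CPU-scale experiments without changing the geometry. ``depth`` counts
    resolution levels and is 5 in the original; the geometry contract
    (572 -> 388) holds only at depth 5.
    """

    in_channels: int = 3
    base_channels: int = 64
    depth: int = 5
    groupnorm_groups: int = 8
    out_channels: int = 1

    def __post_init__(self):
        if self.base_channels % self.groupnorm_groups:
            raise ValueError(
                f"base_channels ({self.base_channels}) must be divisible by "
                f"groupnorm_groups ({self.groupnorm_groups})"
            )
        if self.depth < 2:
            raise ValueError("depth must be >= 2")


def output_side_for_input(input_side: int, depth: int = 5) -> int:
    """Propagate a square tile side through the network arithmetic.

    Each level applies two valid 3x3 convolutions (-2 each); descending
    levels then halve the side (2x2 pooling), ascending levels double it
    (2x2 up-convolution) before their two convolutions.

    Raises ``ValueError`` if any intermediate side is non-positive or odd
    before a pooling step — such inputs cannot be segmented without silent
    rounding.
    """
    s = int(input_side)
    if s != input_side:
        raise ValueError("input side must be an integer")
    for _ in range(depth - 1):
        s -= 4
        if s <= 0:
            raise ValueError(f"input side {input_side} too small for depth {depth}")
        if s % 2:
            raise ValueError(
                f"input side {input_side} is invalid: side {s} is odd before pooling"
            )
        s //= 2
    s -= 4  # bottleneck convolutions
    for _ in range(depth - 1):
        s *= 2
        s -= 4
    if s <= 0:
        raise ValueError(f"input side {input_side} too small for depth {depth}")
    return s


def valid_input_side(input_side: int, depth: int = 5) -> bool:
    try:
        output_side_for_input(input_side, depth)
    except ValueError:
        return False
    return True


def _center_crop(x: np.ndarray, h: int, w: int) -> tuple[np.ndarray, int, int]:
    hs, ws = x.shape[2], x.shape[3]
    r0, c0 = (hs - h) // 2, (ws - w) // 2
    return x[:, :, r0 : r0 + h, c0 : c0 + w], r0, c0


class UNet:
    """The network. Build with :func:`build_unet` for seeded initialization."""

    def __init__(self, config: UNetConfig, rng: np.random.Generator):
        self.config = config
        c0 = config.base_channels
        g = config.groupnorm_groups
        depth = config.depth
        widths = [c0 * 2**i for i in range(depth)]

        def block(cin, cout):
            return [
                ConvValid(cin, cout, rng), ReLU(), GroupNorm(cout, g),
                ConvValid(cout, cout, rng), ReLU(), GroupNorm(cout, g),
            ]

        self.enc_blocks = []
        cin = config.in_channels
        for wdt in widths:
            self.enc_blocks.append(block(cin, wdt))
            cin = wdt
        self.pools = [MaxPool2() for _ in range(depth - 1)]
        self.upconvs = [UpConv2x2(widths[i + 1], widths[i], rng) for i in range(depth - 1)]
        self.dec_blocks = [block(2 * widths[i], widths[i]) for i in range(depth - 1)]
        self.head = ConvValid(widths[0], config.out_channels, rng, k=1)
        self._cache = None

    # -- parameter plumbing ------------------------------------------------
    def _layers(self):
        for blk in self.enc_blocks:
            yield from blk
        yield from self.pools
        yield from self.upconvs
        for blk in self.dec_blocks:
            yield from blk
        yield self.head

    def parameters(self):
        out = []
        for layer in self._layers():
            out.extend(layer.params())
        return out

    def get_weights(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(weights) != len(params):
            raise ValueError("weight list does not match the architecture")
        for p, w in zip(params, weights):
            p.value = w.astype(np.float32).copy()

    @property
    def n_conv_layers(self) -> int:
        """Convolutional layers (3x3 convs + up-convs + final 1x1)."""
        return sum(1 for l in self._layers() if isinstance(l, (ConvValid, UpConv2x2)))

    # -- forward / backward ------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """x: (N, in_channels, H, W) float32 in [-0.5, 0.5] -> probabilities
        (N, out_channels, H-184, W-184) at depth 5."""
        if x.ndim != 4 or x.shape[1] != self.config.in_channels:
            raise ValueError(
                f"expected (N, {self.config.in_channels}, H, W) input, got {x.shape}"
            )
        depth = self.config.depth
        skips = []
        crops = []
        h = x.astype(np.float32, copy=False)
        for i in range(depth):
            for layer in self.enc_blocks[i]:
                h = layer.forward(h, train=train)
            if i < depth - 1:
                skips.append(h)
                h = self.pools[i].forward(h, train=train)
        for i in range(depth - 2, -1, -1):
            h = self.upconvs[i].forward(h, train=train)
            skip = skips[i]
            cropped, r0, c0 = _center_crop(skip, h.shape[2], h.shape[3])
            crops.append((i, skip.shape, r0, c0))
            h = np.concatenate([cropped, h], axis=1)
            for layer in self.dec_blocks[i]:
                h = layer.forward(h, train=train)
        z = self.head.forward(h, train=train)
        p = 1.0 / (1.0 + np.exp(-z))
        if train:
            self._cache = {"p": p, "crops": crops}
        return p

    def backward(self, dp: np.ndarray) -> None:
        """Accumulate parameter gradients given dLoss/dprobabilities."""
        cache = self._cache
        if cache is None:
            raise RuntimeError("backward called without a train-mode forward")
        p = cache["p"]
        dz = (dp * p * (1.0 - p)).astype(np.float32)
        h = self.head.backward(dz)
        depth = self.config.depth
        crops = dict()
        for i, shape, r0, c0 in cache["crops"]:
            crops[i] = (shape, r0, c0)
        dskips = {}
        for i in range(0, depth - 1):
            for layer in reversed(self.dec_blocks[i]):
                h = layer.backward(h)
            nch = h.shape[1] // 2
            dcrop, dh = h[:, :nch], h[:, nch:]
            shape, r0, c0 = crops[i]
            dskip = np.zeros(shape, dtype=np.float32)
            dskip[:, :, r0 : r0 + dcrop.shape[2], c0 : c0 + dcrop.shape[3]] = dcrop
            dskips[i] = dskip
            h = self.upconvs[i].backward(np.ascontiguousarray(dh))
        for i in range(depth - 1, -1, -1):
            if i < depth - 1:
                h = self.pools[i].backward(h)
                h = h + dskips[i]
            for layer in reversed(self.enc_blocks[i]):
                h = layer.backward(h)
        self._cache = None


def build_unet(config: UNetConfig | None = None, seed: int = 0) -> UNet:
    """Construct a U-Net with He-initialized weights drawn from ``seed``."""
    config = config or UNetConfig()
    rng = np.random.default_rng(seed)
    return UNet(config, rng)


def save_model(model: UNet, path) -> None:
    """Write the weights as an .npz archive with the architecture config in a
    sidecar JSON (same path with a .json suffix appended)."""
    import dataclasses
    import json
    from pathlib import Path

    path = Path(path)
    np.savez(path, *model.get_weights())
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(dataclasses.asdict(model.config), indent=2))


def load_model(path) -> UNet:
    """Rebuild a network from :func:`save_model` output."""
    import json
    from pathlib import Path

    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    config = UNetConfig(**json.loads(sidecar.read_text()))
    model = build_unet(config, seed=0)
    with np.load(path) as archive:
        model.set_weights([archive[k] for k in archive.files])
    return model


def predict_tile(model: UNet, tile: np.ndarray) -> np.ndarray:
    """Segment one normalized tile.

    ``tile``: (H, W, 3) float in [-0.5, 0.5] with a geometrically valid side;
    returns the (H-184, W-184) probability map for the tile center.
    """
    tile = np.asarray(tile)
    if tile.ndim != 3 or tile.shape[2] != model.config.in_channels:
        raise ValueError(f"expected (H, W, {model.config.in_channels}) tile, got {tile.shape}")
    if tile.min() < -0.5 - 1e-6 or tile.max() > 0.5 + 1e-6:
        raise ValueError("tile must be normalized to [-0.5, +0.5]")
    for side in tile.shape[:2]:
        output_side_for_input(side, model.config.depth)  # raises if invalid
    x = tile.transpose(2, 0, 1)[None].astype(np.float32)
    p = model.forward(x, train=False)
    return p[0, 0]


def predict_image(model: UNet, image: np.ndarray, tile_out_side: int = 388) -> np.ndarray:
    """Segment a full image by mirror-padding, tiling, and stitching.

    ``image``: (H, W, 3) uint8. The output probability map has the same
    height and width as the input.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("predict_image expects an (H, W, 3) image")
    margin = CONTEXT_MARGIN // 2
    padded = dataprep.mirror_pad(image, margin)
    tiles = dataprep.inference_tiles(padded, out_side=tile_out_side)
    preds = []
    for t in tiles:
        p = predict_tile(model, normalize_tile(t.input_patch))
        preds.append((t.origin, p))
    return dataprep.stitch_predictions(preds, image.shape[0], image.shape[1])
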