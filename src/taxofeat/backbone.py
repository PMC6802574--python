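"""Five-block convolutional backbone with the VGG16 layout.

The backbone is used purely as a fixed feature extractor: an input frame of
side S passes through five blocks c1..c5 of 3x3 convolutions (same padding,
ReLU) each ending in a 2x2 max-pool that halves the spatial extent, so after
block ck the spatial side is S / 2^k. Filter depths are 64, 128, 256, 512,
512. No training or fine-tuning happens here.

Two concrete backbones are provided:

* :func:`load_vgg16_backbone` — the genuine VGG16 ImageNet weights, read
  from a local ``.npz`` file (13 conv kernels + biases). Input frames get
  the canonical VGG preprocessing (RGB->BGR, ImageNet channel means).
* :func:`make_fixture_backbone` — a seeded, small random-weight backbone
  with identical block/shape semantics (one conv layer per block, full
  filter depths). Random convolutional features are not ImageNet features,
  but they preserve color and texture statistics well enough that visually
  distinct categories remain linearly separable, which is what offline
  tests need.

The forward pass is plain numpy: im2col patch extraction plus one matmul
per conv layer.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import BackboneWeightsError, ConfigError, GeometryError

__all__ = [
    "BackboneSpec",
    "FeatureMatrix",
    "Backbone",
    "make_fixture_backbone",
    "load_vgg16_backbone",
    "extract_features",
    "BLOCK_IDS",
]

BLOCK_IDS = ("c1", "c2", "c3", "c4", "c5")

#: ImageNet channel means for the published VGG16 weights (BGR order).
_VGG_BGR_MEANS = np.array([103.939, 116.779, 123.68], dtype=np.float32)


@dataclass(frozen=True)
class BackboneSpec:
    """Block-level architecture: filter depth and conv count per block.

    Every block halves the spatial extent at its end via 2x2 max-pooling,
    so the post-pool side of block ck is S / 2^k.
    """

    filters_per_block: tuple[int, ...] = (64, 128, 256, 512, 512)
    convs_per_block: tuple[int, ...] = (2, 2, 3, 3, 3)

    def __post_init__(self) -> None:
        if len(self.filters_per_block) != 5 or len(self.convs_per_block) != 5:
            raise ConfigError("BackboneSpec requires exactly five blocks")

    def output_shape(self, side: int, block: str, tap_point: str = "post_pool") -> tuple[int, int, int]:
        """Spatial side and depth of a block's feature matrix for input side S."""
        k = _block_index(block) + 1
        if side % 32 != 0:
            raise ConfigError(f"input side {side} is not divisible by 32")
        halvings = k if tap_point == "post_pool" else k - 1
        s = side // (2**halvings)
        return (s, s, self.filters_per_block[k - 1])


@dataclass(frozen=True)
class FeatureMatrix:
    """One block's activation volume (height x width x filter depth)."""

    block_id: str
    tap_point: str  # "pre_pool" | "post_pool"
    values: np.ndarray

    @property
    def spatial_side(self) -> int:
        return self.values.shape[0]

    @property
    def depth(self) -> int:
        return self.values.shape[2]


def _block_index(block: str) -> int:
    if block not in BLOCK_IDS:
        raise ConfigError(f"unknown block {block!r}; expected one of {BLOCK_IDS}")
    return BLOCK_IDS.index(block)


def _conv3x3(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """3x3 same-padding convolution + ReLU. x: H x W x Cin, w: 3 x 3 x Cin x Cout."""
    h, width, cin = x.shape
    xp = np.pad(x, ((1, 1), (1, 1), (0, 0)))
    patches = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(0, 1))
    # patches: H x W x Cin x 3 x 3 -> (H*W) x (3*3*Cin) matching w order (ky, kx, cin)
    cols = patches.transpose(0, 1, 3, 4, 2).reshape(h * width, 9 * cin)
    out = cols @ w.reshape(9 * cin, -1) + b
    np.maximum(out, 0.0, out=out)
    return out.reshape(h, width, -1)


def _maxpool2(x: np.ndarray) -> np.ndarray:
    h, w, c = x.shape
    if h % 2 or w % 2:
        raise GeometryError(f"spatial size {h}x{w} not divisible by 2 for max-pooling")
    return x.reshape(h // 2, 2, w // 2, 2, c).max(axis=(1, 3))


class Backbone:
    """A concrete five-block backbone: weights plus input normalization.

    Feature extraction is a pure function of (weights, image): identical
    inputs always yield bit-identical feature matrices.
    """

    def __init__(
        self,
        spec: BackboneSpec,
        weights: list[list[tuple[np.ndarray, np.ndarray]]],
        input_mode: str = "unit",
        name: str = "backbone",
    ) -> None:
        if len(weights) != 5:
            raise ConfigError("weights must cover exactly five blocks")
        for k, block_ws in enumerate(weights):
            if len(block_ws) != spec.convs_per_block[k]:
                raise ConfigError(
                    f"block c{k + 1} expects {spec.convs_per_block[k]} conv layers, "
                    f"got {len(block_ws)}"
                )
        self.spec = spec
        self.weights = weights
        self.input_mode = input_mode  # "unit" | "vgg"
        self.name = name

    def _normalize_input(self, image: np.ndarray) -> np.ndarray:
        x = np.asarray(image, dtype=np.float32)
        if self.input_mode == "vgg":
            # canonical preprocessing for the published ImageNet weights
            return x[..., ::-1] - _VGG_BGR_MEANS
        return x / 255.0 - 0.5

    def forward(
        self, image: np.ndarray, taps: dict[str, str]
    ) -> dict[str, FeatureMatrix]:
        """Run one forward pass, recording the requested (block, tap_point) outputs.

        ``taps`` maps block id -> "pre_pool" | "post_pool". A single pass
        serves all requested blocks.
        """
        if image.ndim != 3 or image.shape[2] != 3:
            raise ConfigError(f"expected an S x S x 3 image, got shape {image.shape}")
        side = image.shape[0]
        if image.shape[0] != image.shape[1] or side % 32 != 0:
            raise ConfigError(
                f"input must be square with side divisible by 32, got {image.shape[:2]}"
            )
        for blk, tap in taps.items():
            _block_index(blk)
            if tap not in ("pre_pool", "post_pool"):
                raise ConfigError(f"unknown tap point {tap!r}")
        last = max(_block_index(b) for b in taps) if taps else -1
        out: dict[str, FeatureMatrix] = {}
        x = self._normalize_input(image)
        for k in range(last + 1):
            for w, b in self.weights[k]:
                x = _conv3x3(x, w, b)
            blk = BLOCK_IDS[k]
            if taps.get(blk) == "pre_pool":
                out[blk] = FeatureMatrix(blk, "pre_pool", x.copy())
            x = _maxpool2(x)
            if taps.get(blk) == "post_pool":
                out[blk] = FeatureMatrix(blk, "post_pool", x.copy())
        return out


def extract_features(
    backbone: Backbone,
    image: np.ndarray,
    blocks: tuple[str, ...] = ("c5",),
    tap_points: dict[str, str] | None = None,
) -> dict[str, FeatureMatrix]:
    """Per-block feature matrices for ``image``.

    ``tap_points`` overrides the default post_pool tap per block; e.g.
    ``{"c5": "pre_pool"}`` taps c5 before its final max-pool, retaining the
    larger spatial grid.
    """
    taps = {b: "post_pool" for b in blocks}
    if tap_points:
        taps.update({b: t for b, t in tap_points.items() if b in taps})
    return backbone.forward(image, taps)


def make_fixture_backbone(seed: int = 0, spec: BackboneSpec | None = None) -> Backbone:
    """A deterministic random-weight backbone for offline use.

    One conv layer per block, full filter depths, He-scaled Gaussian
    kernels from a seeded generator. Cheap on CPU; same seed -> identical
    weights -> identical features.
    """
    spec = spec or BackboneSpec(convs_per_block=(1, 1, 1, 1, 1))
    rng = np.random.default_rng(seed)
    weights = []
    cin = 3
    for cout in spec.filters_per_block:
        block = []
        for _ in range(spec.convs_per_block[len(weights)]):
            w = rng.standard_normal((3, 3, cin, cout)).astype(np.float32)
            w *= np.sqrt(2.0 / (9 * cin))
            b = rng.standard_normal(cout).astype(np.float32) * 0.01
            block.append((w, b))
            cin = cout
        weights.append(block)
    return Backbone(spec, weights, input_mode="unit", name=f"fixture(seed={seed})")


def load_vgg16_backbone(weights_path: str | Path) -> Backbone:
    """Load the published VGG16 ImageNet convolutional weights from a ``.npz``.

    The archive must hold, for block k (1..5) and conv layer i within the
    block, arrays ``b{k}c{i}_W`` of shape (3, 3, Cin, Cout) and ``b{k}c{i}_b``
    of shape (Cout,) — the 13 convolutional layers of VGG16. The fully
    connected head is not used.

    Raises
    ------
    BackboneWeightsError
        If the file is missing, with a pointer to the fixture backbone.
    """
    weights_path = Path(weights_path)
    if not weights_path.exists():
        raise BackboneWeightsError(
            f"pretrained VGG16 weights not found at {weights_path}; download the "
            "ImageNet weights and convert them to the documented .npz layout, or "
            "use the offline fixture backbone (make_fixture_backbone / "
            "--backbone fixture)"
        )
    spec = BackboneSpec()
    with np.load(weights_path) as npz:
        weights = []
        for k in range(5):
            block = []
            for i in range(spec.convs_per_block[k]):
                try:
                    w = npz[f"b{k + 1}c{i + 1}_W"].astype(np.float32)
                    b = npz[f"b{k + 1}c{i + 1}_b"].astype(np.float32)
                except KeyError as exc:
                    raise BackboneWeightsError(
                        f"weight archive {weights_path} lacks array {exc}"
                    ) from None
                block.append((w, b))
            weights.append(block)
    return Backbone(spec, weights, input_mode="vgg", name="vgg16")
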