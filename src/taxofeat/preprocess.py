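"""Square input frames for the backbone.

Two resize protocols are supported:

``preserve_aspect``
    Scale the image so its larger side equals the target side S, center it in
    an S x S frame, and fill the frame outside the content with random pixel
    values (independent uniform integers on [0, 255] per pixel and channel,
    from a seeded generator). Random filler is deliberately uninformative: a
    constant border would let a classifier read the object's aspect ratio
    from the padding amount.

``distort``
    Resample both dimensions to S independently, changing the aspect ratio.
    No padding.

Backbone-specific input normalization (channel means etc.) is *not* applied
here; it belongs to the backbone adapter so this module stays
backbone-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image

from .errors import ConfigError, InputError

__all__ = ["ResizeSpec", "resize_preserve_aspect", "resize_distort", "preprocess_image"]

#: Default side lengths swept in the image-size experiments.
DEFAULT_SIDES = (128, 224, 320, 416, 512)


@dataclass(frozen=True)
class ResizeSpec:
    """How to produce an S x S x 3 input frame.

    ``target_side`` must be divisible by 32 so that all five max-pool
    halvings of the backbone land on integer spatial sizes.
    """

    target_side: int = 128
    mode: str = "preserve_aspect"  # or "distort"
    pad_seed: int = 0

    def __post_init__(self) -> None:
        if self.target_side < 32 or self.target_side % 32 != 0:
            raise ConfigError(
                f"target_side must be >= 32 and divisible by 32, got {self.target_side}"
            )
        if self.mode not in ("preserve_aspect", "distort"):
            raise ConfigError(f"unknown resize mode {self.mode!r}")


def _check_image(image: np.ndarray) -> None:
    if image.ndim != 3 or image.shape[2] != 3:
        raise InputError(f"expected an H x W x 3 array, got shape {image.shape}")
    if image.shape[0] == 0 or image.shape[1] == 0:
        raise InputError("zero-area image")


def _resample(image: np.ndarray, height: int, width: int) -> np.ndarray:
    """Bilinear resample to (height, width)."""
    im = Image.fromarray(np.ascontiguousarray(image))
    return np.asarray(im.resize((width, height), Image.BILINEAR), dtype=image.dtype)


def resize_preserve_aspect(image: np.ndarray, spec: ResizeSpec) -> np.ndarray:
    """Aspect-preserving resize into a randomly padded S x S frame.

    The scaled content is centered; with odd margins the extra pixel goes to
    the bottom/right. Bit-identical output for a fixed ``spec.pad_seed``.
    """
    _check_image(image)
    s = spec.target_side
    h, w = image.shape[:2]
    if h >= w:
        nh, nw = s, max(1, round(w * s / h))
    else:
        nh, nw = max(1, round(h * s / w)), s
    content = _resample(image, nh, nw)
    rng = np.random.default_rng(spec.pad_seed)
    frame = rng.integers(0, 256, size=(s, s, 3), dtype=np.uint8).astype(image.dtype)
    top = (s - nh) // 2
    left = (s - nw) // 2
    frame[top : top + nh, left : left + nw] = content
    return frame


def resize_distort(image: np.ndarray, spec: ResizeSpec) -> np.ndarray:
    """Resample both dimensions to S, distorting the aspect ratio; no padding."""
    _check_image(image)
    return _resample(image, spec.target_side, spec.target_side)


def preprocess_image(image: np.ndarray, spec: ResizeSpec) -> np.ndarray:
    """Dispatch on ``spec.mode``; always returns an S x S x 3 array."""
    if spec.mode == "preserve_aspect":
        return resize_preserve_aspect(image, spec)
    return resize_distort(image, spec)
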