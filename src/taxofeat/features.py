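"""From block feature matrices to classifier-ready vectors.

Two descriptor schemes are supported.

Global scheme
    Collapse each block's H x W x F volume to a length-F vector by average
    or max pooling over the spatial grid, optionally concatenating several
    blocks (feature fusion).

Intermediate scheme
    Preserve coarse spatial layout between the global (1x1) and raw
    extremes. The last three blocks are first brought to a common spatial
    grid (the reference side is block c4's post-pool side, S/16; c3's
    post-pool output at S/8 is average-pooled 2x2 with stride 2, c4 is used
    as-is, and c5 is tapped *before* its final max-pool so it retains S/16).
    A one-pixel zero border then pads the grid (26 -> 28 for S = 416) so it
    divides evenly into N x N cells for N in {2, 4, 7, 14}; N equal to the
    padded side means flattening with no spatial reduction, and N = 1 is
    plain global pooling of the *unpadded* matrix (the zero border never
    enters an average).

Descriptors may be signed-square-root normalized (sign(x)*sqrt(|x|),
compressing dynamic range, which helps margin classifiers) and optionally
l2-normalized. Flattening order is fixed: spatial row-major with the filter
index fastest; any consistent order is equivalent for a linear classifier,
but caches and models must agree on one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .backbone import FeatureMatrix
from .errors import ConfigError, GeometryError, UsageError

__all__ = [
    "FeatureVector",
    "global_pool",
    "align_to_common_grid",
    "zero_pad_border",
    "spatial_pool",
    "flatten_features",
    "intermediate_vector",
    "fuse",
    "signed_sqrt",
    "l2_normalize",
]

#: Pooling levels supported on the padded 28-grid at S = 416.
INTERMEDIATE_LEVELS = (1, 2, 4, 7, 14, 28)


@dataclass(frozen=True)
class FeatureVector:
    """A 1-D descriptor plus provenance (which image and blocks produced it)."""

    values: np.ndarray
    image_key: str | None = None
    blocks: tuple[str, ...] = ()

    def __len__(self) -> int:
        return self.values.shape[0]


def _values(fm: FeatureMatrix | np.ndarray) -> np.ndarray:
    return fm.values if isinstance(fm, FeatureMatrix) else np.asarray(fm)


def _check_mode(mode: str) -> None:
    if mode not in ("average", "max"):
        raise ConfigError(f"pooling mode must be 'average' or 'max', got {mode!r}")


def global_pool(fm: FeatureMatrix | np.ndarray, mode: str = "average") -> np.ndarray:
    """Collapse H x W x F to a length-F vector by mean or max over the grid."""
    _check_mode(mode)
    v = _values(fm)
    op = np.mean if mode == "average" else np.max
    return op(v, axis=(0, 1))


def align_to_common_grid(fm: FeatureMatrix, reference_side: int) -> np.ndarray:
    """Bring a block's volume to the common spatial grid of the intermediate scheme.

    A volume at twice the reference side (c3 post-pool) is reduced by
    non-overlapping 2x2 average windows with stride 2; a volume already at
    the reference side (c4 post-pool, c5 pre-pool) passes through unchanged.
    """
    v = fm.values
    side = v.shape[0]
    if side == reference_side:
        return v
    if side == 2 * reference_side:
        return v.reshape(reference_side, 2, reference_side, 2, -1).mean(axis=(1, 3))
    raise GeometryError(
        f"block {fm.block_id} ({fm.tap_point}) has spatial side {side}; expected "
        f"{reference_side} or {2 * reference_side}"
    )


def zero_pad_border(fm: np.ndarray) -> np.ndarray:
    """Add a one-pixel zero border on every side of the spatial grid."""
    if fm.ndim != 3:
        raise GeometryError(f"expected H x W x F, got shape {fm.shape}")
    return np.pad(fm, ((1, 1), (1, 1), (0, 0)))


def spatial_pool(fm: np.ndarray, n: int, mode: str = "average") -> np.ndarray:
    """Pool the spatial grid to N x N with non-overlapping equal windows.

    The grid side must be divisible by N (true for N in {2, 4, 7, 14} on
    the padded 28-grid).
    """
    _check_mode(mode)
    side = fm.shape[0]
    if n < 1 or side % n != 0:
        raise ConfigError(f"pooling level {n} does not divide the grid side {side}")
    win = side // n
    blocks = fm.reshape(n, win, n, win, -1)
    op = np.mean if mode == "average" else np.max
    return op(blocks, axis=(1, 3))


def flatten_features(fm: np.ndarray) -> np.ndarray:
    """Flatten N x N x F to length N^2 * F, spatial row-major, filter fastest."""
    return np.asarray(fm).reshape(-1)


def intermediate_vector(
    fm: FeatureMatrix,
    reference_side: int,
    level: int,
    mode: str = "average",
) -> np.ndarray:
    """One block's intermediate-scheme descriptor at pooling level N.

    N = 1 global-pools the unpadded aligned matrix; N equal to the padded
    side flattens without pooling; other levels pool the zero-padded grid.
    """
    aligned = align_to_common_grid(fm, reference_side)
    if level == 1:
        return global_pool(aligned, mode)
    padded = zero_pad_border(aligned)
    if level == padded.shape[0]:
        return flatten_features(padded)
    return flatten_features(spatial_pool(padded, level, mode))


def fuse(vectors: list[FeatureVector]) -> FeatureVector:
    """Concatenate per-block descriptors of one image into a fused descriptor.

    All parts must come from the same image (matching ``image_key`` when
    set); the provenance of the result records the fused block order.
    """
    if not vectors:
        raise UsageError("fuse requires at least one vector")
    keys = {v.image_key for v in vectors if v.image_key is not None}
    if len(keys) > 1:
        raise UsageError(f"cannot fuse vectors from different images: {sorted(keys)}")
    blocks = tuple(b for v in vectors for b in v.blocks)
    key = next(iter(keys)) if keys else None
    return FeatureVector(np.concatenate([v.values for v in vectors]), key, blocks)


def signed_sqrt(v: np.ndarray) -> np.ndarray:
    """Elementwise sign(x) * sqrt(|x|)."""
    v = np.asarray(v)
    return np.sign(v) * np.sqrt(np.abs(v))


def l2_normalize(v: np.ndarray) -> np.ndarray:
    """v / ||v||_2; the zero vector is returned unchanged."""
    v = np.asarray(v, dtype=float)
    norm = np.linalg.norm(v)
    if norm == 0:
        return v.copy()
    return v / norm
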