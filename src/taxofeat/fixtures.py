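"""Synthetic labeled specimen images and feature test sets.

Real specimen datasets have structure that matters to the pipeline: each
category is recognizable by a motif (coloration, markings), images vary in
background, aspect ratio and object scale, and some datasets photograph the
same physical specimen several times, so naive cross-validation leaks
specimens between train and test. The generator reproduces exactly this
structure with parametric "beetles": an elliptical body whose hue, stripe
frequency and white-spot pattern identify the category, drawn on a noisy
background, with per-image scale/translation/rotation jitter and spot
placements shared within a synthetic specimen.

Difficulty controls inter-category distinctness. ``easy`` spreads hues over
the color wheel and uses widely different spot counts. ``hard`` keeps hue
and stripes identical across categories and varies only the number, size
and placement of the white spots — a fine-grained discrimination task in
the spirit of sibling-species identification.

Fixtures test mechanics, not biology: no claim of photorealism is made.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from matplotlib.colors import hsv_to_rgb
from PIL import Image

from .dataset import ImageRecord, Manifest, write_manifest
from .errors import ImageIOError

__all__ = ["FixtureSpec", "generate_image_dataset", "generate_feature_testset"]


@dataclass(frozen=True)
class FixtureSpec:
    """Shape of a synthetic dataset.

    images_per_specimen > 1 emulates datasets that photograph each specimen
    several times (4-5 is typical), making grouped-fold evaluation testable.
    Non-square size ranges exercise aspect-ratio handling.
    """

    n_categories: int = 4
    images_per_category: int = 12
    images_per_specimen: int = 4
    height_range: tuple[int, int] = (96, 160)
    width_range: tuple[int, int] = (96, 160)
    difficulty: str = "easy"  # or "hard"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_categories, self.images_per_category, self.images_per_specimen) < 1:
            raise ValueError("all fixture counts must be >= 1")
        if self.difficulty not in ("easy", "hard"):
            raise ValueError(f"difficulty must be 'easy' or 'hard', got {self.difficulty!r}")


@dataclass(frozen=True)
class _Motif:
    hue: float
    saturation: float
    stripe_freq: float
    spot_count: int
    spot_radius: float  # fraction of the body's minor axis


def _category_motifs(spec: FixtureSpec) -> list[_Motif]:
    k = spec.n_categories
    motifs = []
    for i in range(k):
        if spec.difficulty == "easy":
            motifs.append(
                _Motif(
                    hue=i / k,
                    saturation=0.9,
                    stripe_freq=2.0 + 2.0 * i,
                    spot_count=2 + 3 * i,
                    spot_radius=0.10,
                )
            )
        else:
            # same hue and stripes everywhere; only the spot pattern differs
            motifs.append(
                _Motif(
                    hue=0.08,
                    saturation=0.75,
                    stripe_freq=4.0,
                    spot_count=3 + 3 * i,
                    spot_radius=0.13,
                )
            )
    return motifs


def _render(
    motif: _Motif,
    spot_uv: np.ndarray,
    height: int,
    width: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw one image: noisy background + striped body ellipse + white spots."""
    bg_hue = rng.uniform(0.25, 0.45)  # greenish/greyish lab backgrounds
    bg = hsv_to_rgb([bg_hue, rng.uniform(0.05, 0.2), rng.uniform(0.55, 0.85)])
    img = np.tile(bg, (height, width, 1))
    img += rng.normal(0.0, 0.03, size=img.shape)

    # body placement: scale/translation/rotation jitter per image
    scale = rng.uniform(0.62, 0.88)
    a = 0.5 * scale * width * rng.uniform(0.55, 0.7)  # semi-axis along x
    b = 0.5 * scale * height * rng.uniform(0.8, 1.0)  # semi-axis along y
    cy = height / 2 + rng.uniform(-0.06, 0.06) * height
    cx = width / 2 + rng.uniform(-0.06, 0.06) * width
    theta = rng.uniform(-0.35, 0.35)

    ys, xs = np.mgrid[0:height, 0:width].astype(float)
    dy, dx = ys - cy, xs - cx
    ct, st = math.cos(theta), math.sin(theta)
    xr = ct * dx + st * dy
    yr = -st * dx + ct * dy
    body = (xr / a) ** 2 + (yr / b) ** 2 <= 1.0

    base = hsv_to_rgb([motif.hue, motif.saturation, 0.55])
    stripes = 0.78 + 0.22 * np.sin(motif.stripe_freq * math.pi * yr / b)
    img[body] = base * stripes[body, None]

    # spots live in body-local unit coordinates, shared within a specimen
    r_spot = motif.spot_radius * min(a, b)
    for u, v in spot_uv:
        sy = cy + st * (u * a) + ct * (v * b)
        sx = cx + ct * (u * a) - st * (v * b)
        spot = (ys - sy) ** 2 + (xs - sx) ** 2 <= r_spot**2
        img[spot & body] = 0.97

    return (np.clip(img, 0.0, 1.0) * 255).astype(np.uint8)


def generate_image_dataset(spec: FixtureSpec, out_dir: str | Path) -> Manifest:
    """Write a synthetic dataset (PNG images + ``manifest.csv``) to ``out_dir``.

    Deterministic per ``spec.seed``: the same spec yields bit-identical
    images. Returns the manifest (records carry specimen ids).
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise ImageIOError(f"cannot create output directory {out_dir}: {exc}") from exc
    rng = np.random.default_rng(spec.seed)
    motifs = _category_motifs(spec)
    records = []
    for c, motif in enumerate(motifs):
        label = f"species_{c:02d}"
        cat_dir = out_dir / label
        cat_dir.mkdir(exist_ok=True)
        made = 0
        sidx = 0
        while made < spec.images_per_category:
            sid = f"{label}_sp{sidx:03d}"
            # spot pattern is the specimen's identity within its category
            spot_uv = rng.uniform(-0.65, 0.65, size=(motif.spot_count, 2))
            for _ in range(min(spec.images_per_specimen, spec.images_per_category - made)):
                h = int(rng.integers(spec.height_range[0], spec.height_range[1] + 1))
                w = int(rng.integers(spec.width_range[0], spec.width_range[1] + 1))
                arr = _render(motif, spot_uv, h, w, rng)
                path = cat_dir / f"img_{made:04d}.png"
                Image.fromarray(arr).save(path)
                records.append(ImageRecord(path=path, label=label, specimen_id=sid))
                made += 1
            sidx += 1
    manifest = Manifest(tuple(records))
    write_manifest(manifest, out_dir / "manifest.csv")
    return manifest


def generate_feature_testset(
    n: int, d: int, k: int, separation: float, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian class clusters with controllable separation.

    Class centers are random unit directions scaled by ``separation``;
    points add standard normal noise. Labels are balanced (the first
    ``n % k`` classes absorb any remainder). Deterministic per seed.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    centers = rng.standard_normal((k, d))
    centers /= np.linalg.norm(centers, axis=1, keepdims=True)
    centers *= separation
    counts = [n // k + (1 if i < n % k else 0) for i in range(k)]
    y = np.concatenate([np.full(c, i) for i, c in enumerate(counts)])
    X = centers[y] + rng.standard_normal((n, d))
    return X, y
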