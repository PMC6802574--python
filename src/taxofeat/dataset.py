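"""Dataset manifests and image loading.

A dataset is described by a CSV manifest with columns ``path,label`` and an
optional ``specimen_id`` column marking images that portray the same physical
specimen (several museum datasets photograph each specimen 4-5 times; those
images must travel together through cross-validation folds to avoid
train/test leakage).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .errors import EmptyManifestError, ImageIOError, ManifestFormatError

__all__ = [
    "ImageRecord",
    "Manifest",
    "read_manifest",
    "write_manifest",
    "load_image",
    "average_dimensions",
    "subsample_per_category",
]


@dataclass(frozen=True)
class ImageRecord:
    """One labeled specimen image.

    Parameters
    ----------
    path : Path
        Location of the image file.
    label : str
        Category name (typically a taxon: family, genus or species).
    specimen_id : str, optional
        Identifier shared by all images of one physical specimen.
    """

    path: Path
    label: str
    specimen_id: str | None = None

    def __post_init__(self) -> None:
        if not self.label:
            raise ManifestFormatError("record has an empty label")


@dataclass(frozen=True)
class Manifest:
    """An ordered collection of :class:`ImageRecord`."""

    records: tuple[ImageRecord, ...]

    @property
    def categories(self) -> tuple[str, ...]:
        """Distinct labels in sorted order."""
        return tuple(sorted({r.label for r in self.records}))

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records])

    @property
    def has_specimen_ids(self) -> bool:
        return all(r.specimen_id is not None for r in self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i: int) -> ImageRecord:
        return self.records[i]

    def subset(self, indices: Iterable[int]) -> "Manifest":
        """A new manifest holding the records at ``indices``, in that order."""
        return Manifest(tuple(self.records[i] for i in indices))


def read_manifest(path: str | Path) -> Manifest:
    """Read a manifest CSV (header ``path,label[,specimen_id]``).

    Raises
    ------
    ManifestFormatError
        If a required column is missing.
    EmptyManifestError
        If the file holds no data rows.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        raise EmptyManifestError(f"manifest {path} is empty") from None
    missing = {"path", "label"} - set(frame.columns)
    if missing:
        raise ManifestFormatError(
            f"manifest {path} lacks required column(s): {', '.join(sorted(missing))}"
        )
    if len(frame) == 0:
        raise EmptyManifestError(f"manifest {path} has a header but no records")
    has_sid = "specimen_id" in frame.columns
    base = path.parent
    records = []
    for row in frame.itertuples(index=False):
        p = Path(row.path)
        if not p.is_absolute():
            p = base / p
        sid = getattr(row, "specimen_id", None) if has_sid else None
        if sid is not None and (pd.isna(sid) or sid == ""):
            sid = None
        records.append(ImageRecord(path=p, label=row.label, specimen_id=sid))
    return Manifest(tuple(records))


def write_manifest(manifest: Manifest, path: str | Path) -> None:
    """Write ``manifest`` as CSV; paths are stored relative to the CSV when possible."""
    path = Path(path)
    base = path.parent.resolve()
    rows = []
    for r in manifest:
        p = Path(r.path)
        try:
            p = p.resolve().relative_to(base)
        except ValueError:
            pass
        rows.append({"path": str(p), "label": r.label, "specimen_id": r.specimen_id})
    pd.DataFrame(rows, columns=["path", "label", "specimen_id"]).to_csv(path, index=False)


def load_image(path: str | Path) -> np.ndarray:
    """Load an image as an H x W x 3 uint8 RGB array.

    Grayscale images are replicated to three channels; an alpha channel is
    dropped. JPEG/PNG/TIFF are supported through Pillow's decoders.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            arr = np.asarray(im.convert("RGB"), dtype=np.uint8)
    except (OSError, ValueError) as exc:
        raise ImageIOError(f"could not read image {path}: {exc}") from exc
    return arr


def _image_size(path: Path) -> tuple[int, int]:
    """(height, width) of the stored image, from the header only."""
    try:
        with Image.open(path) as im:
            w, h = im.size
    except (OSError, ValueError) as exc:
        raise ImageIOError(f"could not read image {path}: {exc}") from exc
    return h, w


def average_dimensions(manifest: Manifest) -> tuple[int, int]:
    """Mean stored image height and width, each rounded to the nearest integer.

    Used to pick a dataset-level frame before aspect-preserving resizing.
    """
    if len(manifest) == 0:
        raise EmptyManifestError("cannot average dimensions of an empty manifest")
    sizes = np.array([_image_size(r.path) for r in manifest], dtype=float)
    mh, mw = sizes.mean(axis=0)
    return int(np.rint(mh)), int(np.rint(mw))


def subsample_per_category(
    manifest: Manifest, n_per_category: int, seed: int
) -> Manifest:
    """Draw up to ``n_per_category`` records per category, uniformly without replacement.

    Categories with fewer records keep all of them. The selection is
    deterministic for a fixed ``seed``; record content is never altered, only
    membership. Output preserves the original record order.
    """
    if n_per_category < 1:
        raise ValueError("n_per_category must be >= 1")
    rng = np.random.default_rng(seed)
    keep: set[int] = set()
    labels = manifest.labels
    for cat in manifest.categories:
        idx = np.flatnonzero(labels == cat)
        if len(idx) > n_per_category:
            idx = rng.choice(idx, size=n_per_category, replace=False)
        keep.update(int(i) for i in idx)
    return manifest.subset(sorted(keep))
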