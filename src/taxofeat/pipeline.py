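"""Glue: manifest -> preprocessed frames -> block features -> descriptors -> report.

Extracted block features can be cached on disk keyed by everything that
determines them (backbone identity, image size, resize protocol, padding
seed, block, tap point, image path), so the descriptor/classifier ablation
grid re-runs without repeating forward passes.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .backbone import Backbone, FeatureMatrix, load_vgg16_backbone, make_fixture_backbone
from .config import PipelineConfig
from .dataset import Manifest, load_image
from .errors import ConfigError
from .evaluation import (
    EvaluationReport,
    FoldPlan,
    cross_validate,
    grouped_folds,
    stratified_folds,
)
from .features import (
    FeatureVector,
    fuse,
    global_pool,
    intermediate_vector,
    l2_normalize,
    signed_sqrt,
)
from .preprocess import ResizeSpec, preprocess_image

__all__ = [
    "build_backbone",
    "required_taps",
    "FeatureCache",
    "extract_dataset_features",
    "compute_descriptors",
    "make_fold_plan",
    "evaluate",
    "run_grid",
]


def build_backbone(config: PipelineConfig) -> Backbone:
    if config.backbone == "fixture":
        return make_fixture_backbone(config.backbone_seed)
    if config.weights_path is None:
        raise ConfigError("backbone 'vgg16' requires weights_path")
    return load_vgg16_backbone(config.weights_path)


def required_taps(config: PipelineConfig) -> dict[str, str]:
    """Block -> tap point needed for the configured descriptor scheme.

    The intermediate scheme taps c5 before its final max-pool so it keeps
    the common grid side; everything else taps post-pool.
    """
    if config.scheme == "global":
        return {b: "post_pool" for b in config.fusion}
    return {b: ("pre_pool" if b == "c5" else "post_pool") for b in config.fusion}


class FeatureCache:
    """Per-image, per-tap feature matrices as .npz files under a directory."""

    def __init__(self, directory: str | Path) -> None:
        self.directory = Path(directory)
        self.directory.mkdir(parents=True, exist_ok=True)

    def _path(self, key: dict) -> Path:
        blob = json.dumps(key, sort_keys=True).encode()
        return self.directory / (hashlib.sha1(blob).hexdigest() + ".npz")

    def get(self, key: dict) -> np.ndarray | None:
        p = self._path(key)
        if not p.exists():
            return None
        with np.load(p) as npz:
            return npz["values"]

    def put(self, key: dict, values: np.ndarray) -> None:
        np.savez_compressed(self._path(key), values=values.astype(np.float32))


def _record_pad_seed(base: int, index: int) -> int:
    # independent padding noise per record, deterministic in (base, index)
    return int((base * 1_000_003 + index) % 2**31)


def extract_dataset_features(
    manifest: Manifest,
    config: PipelineConfig,
    taps: dict[str, str],
    backbone: Backbone | None = None,
    cache: FeatureCache | None = None,
) -> list[dict[str, FeatureMatrix]]:
    """One dict of block feature matrices per record, in manifest order."""
    backbone = backbone or build_backbone(config)
    if cache is None and config.cache_dir:
        cache = FeatureCache(config.cache_dir)
    out: list[dict[str, FeatureMatrix]] = []
    for i, record in enumerate(manifest):
        pad_seed = _record_pad_seed(config.pad_seed, i)
        base_key = {
            "backbone": backbone.name,
            "size": config.image_size,
            "mode": config.resize_mode,
            "pad_seed": pad_seed,
            "path": str(record.path),
        }
        fmats: dict[str, FeatureMatrix] = {}
        todo: dict[str, str] = {}
        for block, tap in taps.items():
            cached = cache.get({**base_key, "block": block, "tap": tap}) if cache else None
            if cached is not None:
                fmats[block] = FeatureMatrix(block, tap, cached)
            else:
                todo[block] = tap
        if todo:
            spec = ResizeSpec(config.image_size, config.resize_mode, pad_seed)
            frame = preprocess_image(load_image(record.path), spec)
            fresh = backbone.forward(frame, todo)
            for block, fm in fresh.items():
                if cache:
                    cache.put({**base_key, "block": block, "tap": taps[block]}, fm.values)
                fmats[block] = fm
        out.append(fmats)
    return out


def descriptor_from_matrices(
    fmats: dict[str, FeatureMatrix],
    config: PipelineConfig,
    image_key: str | None = None,
) -> np.ndarray:
    """Build one image's descriptor from its block feature matrices."""
    parts = []
    reference_side = config.image_size // 16  # c4's post-pool side
    for block in config.fusion:
        fm = fmats[block]
        if config.scheme == "global":
            vec = global_pool(fm, config.pooling_mode)
        else:
            vec = intermediate_vector(
                fm, reference_side, config.pooling_level, config.pooling_mode
            )
        parts.append(FeatureVector(vec, image_key, (block,)))
    v = fuse(parts).values
    if config.signed_sqrt:
        v = signed_sqrt(v)
    if config.l2:
        v = l2_normalize(v)
    return v


def compute_descriptors(
    manifest: Manifest,
    config: PipelineConfig,
    backbone: Backbone | None = None,
    matrices: list[dict[str, FeatureMatrix]] | None = None,
) -> np.ndarray:
    """n x d descriptor matrix for the whole manifest."""
    if matrices is None:
        matrices = extract_dataset_features(
            manifest, config, required_taps(config), backbone
        )
    rows = [
        descriptor_from_matrices(fmats, config, str(rec.path))
        for rec, fmats in zip(manifest, matrices)
    ]
    return np.stack(rows)


def make_fold_plan(manifest: Manifest, config: PipelineConfig) -> FoldPlan:
    if config.grouping == "by_specimen":
        return grouped_folds(manifest, config.folds, config.fold_seed)
    return stratified_folds(manifest, config.folds, config.fold_seed)


def evaluate(
    manifest: Manifest,
    config: PipelineConfig,
    backbone: Backbone | None = None,
    matrices: list[dict[str, FeatureMatrix]] | None = None,
) -> tuple[EvaluationReport, FoldPlan]:
    """Cross-validated evaluation of the configured pipeline on a manifest."""
    X = compute_descriptors(manifest, config, backbone, matrices)
    plan = make_fold_plan(manifest, config)
    report = cross_validate(X, manifest.labels, plan, config.train_config)
    return report, plan


def run_grid(
    manifest: Manifest,
    base_config: PipelineConfig,
    variants: list[dict],
) -> pd.DataFrame:
    """Evaluate several descriptor configurations sharing one set of forward passes.

    ``variants`` is a list of override dicts (descriptor-level keys such as
    scheme, pooling_mode, pooling_level, fusion, signed_sqrt, l2). Block
    features are extracted once for the union of required taps; the fold
    plan is shared so rows are directly comparable. Returns a tidy frame of
    (overrides..., accuracy, error_rate).
    """
    configs = [base_config.with_overrides(**v) for v in variants]
    union_taps: dict[str, str] = {}
    for cfg in configs:
        for block, tap in required_taps(cfg).items():
            if union_taps.get(block, tap) != tap:
                raise ConfigError(
                    f"grid variants disagree on the tap point for block {block}"
                )
            union_taps[block] = tap
    backbone = build_backbone(base_config)
    matrices = extract_dataset_features(manifest, base_config, union_taps, backbone)
    plan = make_fold_plan(manifest, base_config)
    rows = []
    for overrides, cfg in zip(variants, configs):
        X = compute_descriptors(manifest, cfg, backbone, matrices)
        report = cross_validate(X, manifest.labels, plan, cfg.train_config)
        row = dict(overrides)
        if "fusion" in row:
            row["fusion"] = "+".join(cfg.fusion)
        row["accuracy"] = report.accuracy
        row["error_rate"] = report.error_rate
        rows.append(row)
    return pd.DataFrame(rows)
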