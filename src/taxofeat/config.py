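"""Declarative pipeline configuration.

A single config object records every choice that affects the result —
image size, resize protocol, backbone, descriptor scheme, pooling, fusion,
normalization, classifier settings, fold construction and every seed — so
a run can be reproduced from its run manifest alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

import yaml

from .classifier import TrainConfig
from .errors import ConfigError

__all__ = ["PipelineConfig", "load_config"]

_VALID_BLOCKS = ("c1", "c2", "c3", "c4", "c5")
_INTERMEDIATE_BLOCKS = ("c3", "c4", "c5")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to turn a manifest into an evaluation report.

    scheme
        ``global``: average/max-pool each fused block's post-pool volume to
        one value per filter. ``intermediate``: bring c3/c4/c5 to a common
        grid (c5 tapped pre-pool), zero-pad one pixel, pool to N x N and
        flatten; ``pooling_level`` is the N.
    """

    image_size: int = 128
    resize_mode: str = "preserve_aspect"
    backbone: str = "fixture"  # "fixture" | "vgg16"
    backbone_seed: int = 0
    weights_path: str | None = None
    scheme: str = "global"  # "global" | "intermediate"
    pooling_mode: str = "average"  # "average" | "max"
    pooling_level: int = 1
    fusion: tuple[str, ...] = ("c4",)
    signed_sqrt: bool = True
    l2: bool = False
    svm_c: float = 1.0
    svm_tol: float = 1e-4
    svm_max_iter: int = 10000
    svm_seed: int = 0
    folds: int = 10
    grouping: str = "none"  # "none" | "by_specimen"
    fold_seed: int = 0
    pad_seed: int = 0
    cache_dir: str | None = None

    def __post_init__(self) -> None:
        if self.image_size < 32 or self.image_size % 32:
            raise ConfigError(f"image_size must be divisible by 32, got {self.image_size}")
        if self.resize_mode not in ("preserve_aspect", "distort"):
            raise ConfigError(f"unknown resize_mode {self.resize_mode!r}")
        if self.backbone not in ("fixture", "vgg16"):
            raise ConfigError(f"unknown backbone {self.backbone!r}")
        if self.scheme not in ("global", "intermediate"):
            raise ConfigError(f"unknown scheme {self.scheme!r}")
        if self.pooling_mode not in ("average", "max"):
            raise ConfigError(f"unknown pooling_mode {self.pooling_mode!r}")
        bad = [b for b in self.fusion if b not in _VALID_BLOCKS]
        if bad or not self.fusion:
            raise ConfigError(f"fusion must be a non-empty subset of {_VALID_BLOCKS}")
        if self.scheme == "intermediate":
            bad = [b for b in self.fusion if b not in _INTERMEDIATE_BLOCKS]
            if bad:
                raise ConfigError(
                    f"intermediate scheme supports blocks {_INTERMEDIATE_BLOCKS}, got {bad}"
                )
            side = self.image_size // 16 + 2  # padded common grid
            if self.pooling_level != 1 and side % self.pooling_level:
                raise ConfigError(
                    f"pooling_level {self.pooling_level} does not divide the padded "
                    f"grid side {side} at image_size {self.image_size}"
                )
        elif self.pooling_level != 1:
            raise ConfigError("global scheme implies pooling_level 1")
        if self.grouping not in ("none", "by_specimen"):
            raise ConfigError(f"unknown grouping {self.grouping!r}")
        if self.folds < 2:
            raise ConfigError("folds must be >= 2")

    @property
    def train_config(self) -> TrainConfig:
        return TrainConfig(
            C=self.svm_c, tol=self.svm_tol, max_iter=self.svm_max_iter, seed=self.svm_seed
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fusion"] = list(self.fusion)
        return d

    def config_hash(self) -> str:
        """Stable short hash identifying this configuration for provenance."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        if "fusion" in kwargs and kwargs["fusion"] is not None:
            kwargs["fusion"] = tuple(kwargs["fusion"])
        return replace(self, **{k: v for k, v in kwargs.items() if v is not None})


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Build a config from an optional YAML file plus keyword overrides.

    Unknown keys in the file raise a :class:`ConfigError` listing them.
    """
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(PipelineConfig)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {', '.join(sorted(unknown))}")
    data.update({k: v for k, v in overrides.items() if v is not None})
    if "fusion" in data and data["fusion"] is not None:
        data["fusion"] = tuple(data["fusion"])
    return PipelineConfig(**data)
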