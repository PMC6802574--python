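"""Linear one-vs-rest max-margin classification of feature descriptors.

A linear SVM (squared hinge loss, one binary max-margin classifier per
category) is the standard lightweight head for feature transfer: with tens
of thousands of descriptor dimensions and modest sample counts, classes are
often linearly separable and anything heavier overfits. One-vs-rest scales
linearly with the number of categories, which matters for taxonomic tasks
with hundreds of classes.

The chosen solver provides decision scores, not probabilities; top-k
suggestion lists are therefore ranked by raw decision score, with exact
ties broken by ascending category order.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from sklearn.svm import LinearSVC

from .errors import InputError, UsageError

__all__ = ["TrainConfig", "LinearModel", "train", "decision_scores", "predict", "top_k"]


@dataclass(frozen=True)
class TrainConfig:
    """Solver settings; defaults mirror the common library defaults.

    C : inverse regularization strength (1.0 — no tuning is done).
    loss : "squared_hinge".
    tol : stopping tolerance (1e-4).
    max_iter : generous cap so the solver converges on large descriptors.
    seed : controls any solver-internal randomness; fixed seed means
        deterministic retraining.
    """

    C: float = 1.0
    loss: str = "squared_hinge"
    tol: float = 1e-4
    max_iter: int = 10000
    seed: int = 0


@dataclass(frozen=True)
class LinearModel:
    """One (weight, bias) pair per category; category order fixed at training."""

    coef: np.ndarray  # K x d
    intercept: np.ndarray  # K
    categories: tuple[str, ...]
    config: TrainConfig

    @property
    def n_categories(self) -> int:
        return len(self.categories)

    def save(self, path: str | Path) -> None:
        np.savez(
            Path(path),
            coef=self.coef,
            intercept=self.intercept,
            categories=np.array(self.categories),
            config=json.dumps(asdict(self.config)),
        )

    @classmethod
    def load(cls, path: str | Path) -> "LinearModel":
        with np.load(Path(path)) as npz:
            return cls(
                coef=npz["coef"],
                intercept=npz["intercept"],
                categories=tuple(npz["categories"].tolist()),
                config=TrainConfig(**json.loads(str(npz["config"]))),
            )


def train(features: np.ndarray, labels, config: TrainConfig | None = None) -> LinearModel:
    """Fit a linear one-vs-rest max-margin model.

    Categories are ordered by sorted label; binary problems are expanded to
    two mirrored score functions so every category has its own (w, b).
    """
    config = config or TrainConfig()
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    if X.ndim != 2 or X.shape[1] < 1:
        raise InputError(f"features must be n x d with d >= 1, got shape {X.shape}")
    if not np.all(np.isfinite(X)):
        raise InputError("features contain NaN or infinite values")
    cats = tuple(sorted(np.unique(y).tolist()))
    if len(cats) < 2:
        raise InputError("training requires at least two categories")
    svc = LinearSVC(
        C=config.C,
        loss=config.loss,
        tol=config.tol,
        max_iter=config.max_iter,
        random_state=config.seed,
    )
    svc.fit(X, y)
    coef, intercept = svc.coef_, svc.intercept_
    if len(cats) == 2:
        # sklearn fits one boundary for binary problems; mirror it per category
        coef = np.vstack([-coef, coef])
        intercept = np.concatenate([-intercept, intercept])
    return LinearModel(coef=coef, intercept=intercept, categories=cats, config=config)


def decision_scores(model: LinearModel, features: np.ndarray) -> np.ndarray:
    """n x K matrix of per-category scores w_k . x_i + b_k."""
    X = np.atleast_2d(np.asarray(features, dtype=np.float64))
    if X.shape[1] != model.coef.shape[1]:
        raise UsageError(
            f"feature dimension {X.shape[1]} does not match model dimension "
            f"{model.coef.shape[1]}"
        )
    return X @ model.coef.T + model.intercept


def predict(model: LinearModel, features: np.ndarray) -> np.ndarray:
    """Highest-scoring category per sample (ties -> earliest category order)."""
    scores = decision_scores(model, features)
    idx = np.argmax(scores, axis=1)  # argmax takes the first maximum: the tie rule
    return np.array(model.categories)[idx]


def top_k(model: LinearModel, features: np.ndarray, k: int) -> list[tuple[str, ...]]:
    """Per-sample lists of the k categories with the highest decision scores.

    Ranked by descending score; exact ties broken by ascending category
    order (stable sort on the already category-ordered score row).
    """
    if not 1 <= k <= model.n_categories:
        raise UsageError(f"k must be in [1, {model.n_categories}], got {k}")
    scores = decision_scores(model, features)
    order = np.argsort(-scores, axis=1, kind="stable")[:, :k]
    cats = np.array(model.categories)
    return [tuple(cats[row]) for row in order]
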