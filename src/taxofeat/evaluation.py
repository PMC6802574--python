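"""Cross-validated evaluation and diagnostic reports.

Folds are built by stratified random sampling so each category keeps the
same proportion in every fold (per-category counts differ by at most one
across folds). When the dataset photographs each specimen several times,
grouped folds keep all images of a specimen in one fold, preventing a
classifier from being rewarded for memorizing individual specimens.

Cross-validation is the standard k-fold procedure: each fold serves once as
the held-out test set while the model trains on the other k-1 folds.
Reported accuracy is the proportion of predicted labels exactly matching
the true labels, pooled over all folds; error rate is its complement.
Diagnostics include per-category accuracy vs. sample count, top-k
suggestion correctness (cumulative and per-rank), and a t-SNE map of the
descriptor space (unsupervised — labels only color the points).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.manifold import TSNE

from .classifier import TrainConfig, decision_scores, top_k, train
from .dataset import Manifest
from .errors import UsageError

__all__ = [
    "FoldPlan",
    "EvaluationReport",
    "stratified_folds",
    "grouped_folds",
    "cross_validate",
    "accuracy_by_category",
    "tsne_embed",
]


@dataclass(frozen=True)
class FoldPlan:
    """Fold index per record; every record belongs to exactly one fold."""

    assignments: np.ndarray  # int fold index per record
    k: int
    grouping: str = "none"  # "none" | "by_specimen"
    seed: int = 0

    def __post_init__(self) -> None:
        a = self.assignments
        if a.min() < 0 or a.max() >= self.k:
            raise UsageError("fold assignments outside [0, k)")

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments != fold)


def _deal(indices: np.ndarray, k: int, rng: np.random.Generator, out: np.ndarray) -> None:
    """Shuffle then deal indices round-robin to folds 0..k-1 (remainders to the
    lowest-indexed folds)."""
    perm = rng.permutation(indices)
    for pos, idx in enumerate(perm):
        out[idx] = pos % k


def stratified_folds(manifest: Manifest, k: int = 10, seed: int = 0) -> FoldPlan:
    """Stratified k-fold plan: per-category counts differ by at most 1 across folds.

    Categories with fewer than k records are simply absent from some test
    folds; a warning is emitted rather than an error.
    """
    if k < 2:
        raise UsageError("k must be >= 2")
    labels = manifest.labels
    assignments = np.full(len(manifest), -1, dtype=int)
    rng = np.random.default_rng(seed)
    for cat in manifest.categories:
        idx = np.flatnonzero(labels == cat)
        if len(idx) < k:
            warnings.warn(
                f"category {cat!r} has {len(idx)} records < k={k}; it will be "
                "missing from some test folds",
                stacklevel=2,
            )
        _deal(idx, k, rng, assignments)
    return FoldPlan(assignments, k, "none", seed)


def grouped_folds(manifest: Manifest, k: int = 10, seed: int = 0) -> FoldPlan:
    """Specimen-grouped k-fold plan.

    Specimens (not images) are stratified by category and dealt to folds,
    so no specimen ever spans a train/test split.
    """
    if k < 2:
        raise UsageError("k must be >= 2")
    if not manifest.has_specimen_ids:
        raise UsageError("grouped folds require specimen_id on every record")
    sids = np.array([r.specimen_id for r in manifest])
    specimens = pd.unique(sids)
    spec_label = {s: manifest[int(np.flatnonzero(sids == s)[0])].label for s in specimens}
    spec_fold = np.full(len(specimens), -1, dtype=int)
    spec_index = {s: i for i, s in enumerate(specimens)}
    rng = np.random.default_rng(seed)
    for cat in manifest.categories:
        cat_specs = np.array([spec_index[s] for s in specimens if spec_label[s] == cat])
        if len(cat_specs):
            _deal(cat_specs, k, rng, spec_fold)
    assignments = np.array([spec_fold[spec_index[s]] for s in sids])
    return FoldPlan(assignments, k, "by_specimen", seed)


@dataclass
class EvaluationReport:
    """Pooled and per-fold accuracy plus the diagnostic tables."""

    accuracy: float
    error_rate: float
    fold_accuracies: list[float]
    confusion: pd.DataFrame  # true x predicted counts
    top_k_cumulative: dict[int, float]  # k -> proportion correct within top k
    top_k_per_rank: dict[int, float]  # rank -> proportion correct exactly at rank
    predictions: pd.DataFrame  # index, label, predicted, fold
    missing_category_folds: list[tuple[int, str]] = field(default_factory=list)

    def summary(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "error_rate": self.error_rate,
            "fold_accuracies": self.fold_accuracies,
            "top_k_cumulative": {str(k): v for k, v in self.top_k_cumulative.items()},
            "top_k_per_rank": {str(k): v for k, v in self.top_k_per_rank.items()},
            "missing_category_folds": [
                {"fold": f, "category": c} for f, c in self.missing_category_folds
            ],
        }


def cross_validate(
    features: np.ndarray,
    labels,
    plan: FoldPlan,
    config: TrainConfig | None = None,
    max_suggestions: int = 3,
) -> EvaluationReport:
    """k-fold cross-validation of the linear classifier on precomputed descriptors.

    For each fold, the model trains on the other folds and predicts the
    held-out records. A training split missing a category is recorded in
    the report but the fold is still evaluated.
    """
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    if len(y) != len(plan.assignments):
        raise UsageError("fold plan length does not match number of samples")
    cats = sorted(np.unique(y).tolist())
    n = len(y)
    predicted = np.empty(n, dtype=object)
    true_rank = np.full(n, np.inf)  # 1-based rank of the true label in suggestions
    fold_acc: list[float] = []
    missing: list[tuple[int, str]] = []
    for fold in range(plan.k):
        tr, te = plan.train_indices(fold), plan.test_indices(fold)
        if len(te) == 0:
            continue
        train_cats = set(np.unique(y[tr]))
        for c in cats:
            if c not in train_cats:
                missing.append((fold, c))
        model = train(X[tr], y[tr], config)
        kk = min(max_suggestions, model.n_categories)
        suggestions = top_k(model, X[te], kk)
        for i, idx in enumerate(te):
            predicted[idx] = suggestions[i][0]
            if y[idx] in suggestions[i]:
                true_rank[idx] = suggestions[i].index(y[idx]) + 1
        fold_acc.append(float(np.mean(predicted[te] == y[te])))
    accuracy = float(np.mean(predicted == y))
    confusion = (
        pd.crosstab(pd.Series(y, name="true"), pd.Series(predicted, name="predicted"))
        .reindex(index=cats, columns=cats, fill_value=0)
    )
    ks = range(1, min(max_suggestions, len(cats)) + 1)
    top_cum = {k: float(np.mean(true_rank <= k)) for k in ks}
    top_rank = {k: float(np.mean(true_rank == k)) for k in ks}
    preds = pd.DataFrame(
        {"label": y, "predicted": predicted, "fold": plan.assignments}
    )
    return EvaluationReport(
        accuracy=accuracy,
        error_rate=1.0 - accuracy,
        fold_accuracies=fold_acc,
        confusion=confusion,
        top_k_cumulative=top_cum,
        top_k_per_rank=top_rank,
        predictions=preds,
        missing_category_folds=missing,
    )


def accuracy_by_category(report: EvaluationReport) -> pd.DataFrame:
    """Per-category table (category, n_images, accuracy) from the confusion counts.

    Suitable for scatter-plotting identification accuracy against the
    number of images available per category.
    """
    conf = report.confusion
    n = conf.sum(axis=1)
    correct = pd.Series(np.diag(conf.values), index=conf.index)
    return pd.DataFrame(
        {
            "category": conf.index,
            "n_images": n.values,
            "accuracy": (correct / n.replace(0, np.nan)).values,
        }
    ).reset_index(drop=True)


def tsne_embed(features: np.ndarray, seed: int = 0, perplexity: float = 30.0) -> np.ndarray:
    """2-D t-SNE embedding of descriptors; labels are never used.

    Deterministic for a fixed seed. Perplexity is clamped below n/3 for
    small inputs.
    """
    X = np.asarray(features, dtype=np.float64)
    n = X.shape[0]
    if n < 5:
        raise UsageError(f"t-SNE needs at least 5 samples, got {n}")
    perp = min(perplexity, max(2.0, (n - 1) / 3.0))
    tsne = TSNE(
        n_components=2,
        perplexity=perp,
        init="pca",
        random_state=seed,
        n_jobs=1,
    )
    return tsne.fit_transform(X)
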