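"""Fold construction, cross-validated reports and the t-SNE embedding."""

import numpy as np
import pytest

import taxofeat as tf
from taxofeat.errors import UsageError
from taxofeat.fixtures import generate_feature_testset


def _manifest(counts: dict[str, int], specimens_of: int | None = None):
    records = []
    for label, n in counts.items():
        for i in range(n):
            sid = f"{label}_s{i // specimens_of}" if specimens_of else None
            records.append(tf.ImageRecord(f"{label}_{i}.png", label, sid))
    return tf.Manifest(tuple(records))


class TestStratifiedFolds:
    def test_balanced_square_case(self):
        m = _manifest({f"c{i}": 10 for i in range(10)})
        plan = tf.stratified_folds(m, k=10, seed=0)
        labels = m.labels
        for fold in range(10):
            te = plan.test_indices(fold)
            assert len(te) == 10
            counts = {c: (labels[te] == c).sum() for c in m.categories}
            assert all(v == 1 for v in counts.values())

    def test_remainder_spread_within_one(self):
        m = _manifest({"a": 23, "b": 40})
        plan = tf.stratified_folds(m, k=10, seed=1)
        labels = m.labels
        a_counts = [(labels[plan.test_indices(f)] == "a").sum() for f in range(10)]
        assert set(a_counts) <= {2, 3}

    def test_partition_and_determinism(self):
        m = _manifest({"a": 17, "b": 31, "c": 8})
        p1 = tf.stratified_folds(m, k=5, seed=9)
        p2 = tf.stratified_folds(m, k=5, seed=9)
        p3 = tf.stratified_folds(m, k=5, seed=10)
        assert np.array_equal(p1.assignments, p2.assignments)
        assert not np.array_equal(p1.assignments, p3.assignments)
        covered = np.concatenate([p1.test_indices(f) for f in range(5)])
        assert sorted(covered) == list(range(len(m)))

    def test_small_category_warns_not_errors(self):
        m = _manifest({"a": 3, "b": 20})
        with pytest.warns(UserWarning, match="missing from some test folds"):
            tf.stratified_folds(m, k=10, seed=0)


class TestGroupedFolds:
    def test_specimen_never_spans_folds(self):
        m = _manifest({"a": 20, "b": 25}, specimens_of=5)
        plan = tf.grouped_folds(m, k=5, seed=0)
        sids = np.array([r.specimen_id for r in m])
        for sid in np.unique(sids):
            assert len(np.unique(plan.assignments[sids == sid])) == 1

    def test_specimens_stratified_per_category(self):
        # 20 specimens of one category over 10 folds -> 2 specimens per fold
        m = _manifest({"a": 80}, specimens_of=4)  # 20 specimens x 4 images
        plan = tf.grouped_folds(m, k=10, seed=3)
        sids = np.array([r.specimen_id for r in m])
        per_fold = [
            len(np.unique(sids[plan.test_indices(f)])) for f in range(10)
        ]
        assert per_fold == [2] * 10

    def test_no_leakage_between_train_and_test(self, easy_manifest):
        plan = tf.grouped_folds(easy_manifest, k=3, seed=0)
        sids = np.array([r.specimen_id for r in easy_manifest])
        for f in range(3):
            assert not set(sids[plan.train_indices(f)]) & set(sids[plan.test_indices(f)])

    def test_missing_specimen_id_is_usage_error(self):
        m = _manifest({"a": 6, "b": 6})
        with pytest.raises(UsageError):
            tf.grouped_folds(m, k=3, seed=0)


class TestCrossValidate:
    def test_label_encoding_features_give_perfect_accuracy(self):
        y = np.repeat(np.array(["a", "b", "c"]), 12)
        X = (y[:, None] == np.array(["a", "b", "c"])[None, :]).astype(float) * 10
        plan = tf.stratified_folds(
            tf.Manifest(tuple(tf.ImageRecord(f"{i}.png", lab) for i, lab in enumerate(y))),
            k=4, seed=0,
        )
        report = tf.cross_validate(X, y, plan)
        assert report.accuracy == 1.0
        assert report.error_rate == 0.0

    def test_accuracy_is_hand_counted_match_proportion(self):
        """Pooled accuracy equals a by-hand recount of exact label matches."""
        X, y = generate_feature_testset(n=12, d=3, k=3, separation=1.2, seed=4)
        m = tf.Manifest(tuple(tf.ImageRecord(f"{i}.png", str(l)) for i, l in enumerate(y)))
        plan = tf.stratified_folds(m, k=2, seed=0)
        report = tf.cross_validate(X, y.astype(str), plan)
        correct = sum(
            1 for _, row in report.predictions.iterrows() if row.label == row.predicted
        )
        assert report.accuracy == correct / 12
        assert report.error_rate == 1 - report.accuracy

    def test_top_k_correctness_is_monotone(self):
        X, y = generate_feature_testset(n=80, d=6, k=4, separation=1.0, seed=6)
        m = tf.Manifest(tuple(tf.ImageRecord(f"{i}.png", str(l)) for i, l in enumerate(y)))
        plan = tf.stratified_folds(m, k=4, seed=1)
        report = tf.cross_validate(X, y.astype(str), plan)
        assert report.top_k_cumulative[1] <= report.top_k_cumulative[2] <= report.top_k_cumulative[3]
        assert report.top_k_cumulative[1] == report.accuracy
        # cumulative top-k is the running sum of the per-rank breakdown
        assert np.isclose(
            report.top_k_cumulative[3],
            sum(report.top_k_per_rank[k] for k in (1, 2, 3)),
        )

    def test_pooled_accuracy_matches_confusion_recount(self):
        X, y = generate_feature_testset(n=60, d=4, k=3, separation=1.5, seed=8)
        m = tf.Manifest(tuple(tf.ImageRecord(f"{i}.png", str(l)) for i, l in enumerate(y)))
        plan = tf.stratified_folds(m, k=3, seed=2)
        report = tf.cross_validate(X, y.astype(str), plan)
        conf = report.confusion.values
        assert report.accuracy == np.trace(conf) / conf.sum()

    def test_order_invariance_given_fixed_plan(self):
        X, y = generate_feature_testset(n=40, d=4, k=2, separation=2.0, seed=9)
        m = tf.Manifest(tuple(tf.ImageRecord(f"{i}.png", str(l)) for i, l in enumerate(y)))
        plan = tf.stratified_folds(m, k=4, seed=5)
        base = tf.cross_validate(X, y.astype(str), plan)
        perm = np.random.default_rng(0).permutation(len(y))
        permuted_plan = tf.FoldPlan(plan.assignments[perm], plan.k, plan.grouping, plan.seed)
        permuted = tf.cross_validate(X[perm], y[perm].astype(str), permuted_plan)
        assert np.isclose(base.accuracy, permuted.accuracy)

    def test_missing_category_recorded_not_fatal(self):
        # a singleton category is absent from the training split of the one
        # fold that holds its record; the fold is still evaluated
        y = np.array(["a"] + ["b"] * 8 + ["c"] * 8)
        X = (y[:, None] == np.array(["a", "b", "c"])[None, :]).astype(float) * 5
        m = tf.Manifest(tuple(tf.ImageRecord(f"{i}.png", lab) for i, lab in enumerate(y)))
        with pytest.warns(UserWarning):
            plan = tf.stratified_folds(m, k=4, seed=0)
        report = tf.cross_validate(X, y, plan)
        assert any(cat == "a" for _, cat in report.missing_category_folds)
        assert len(report.fold_accuracies) == 4


class TestAccuracyByCategory:
    def _report(self, sep, seed=11):
        X, y = generate_feature_testset(n=60, d=5, k=3, separation=sep, seed=seed)
        m = tf.Manifest(tuple(tf.ImageRecord(f"{i}.png", str(l)) for i, l in enumerate(y)))
        plan = tf.stratified_folds(m, k=3, seed=0)
        return tf.cross_validate(X, y.astype(str), plan)

    def test_perfect_case_all_ones(self):
        table = tf.accuracy_by_category(self._report(sep=30.0))
        assert np.allclose(table.accuracy, 1.0)

    def test_counts_sum_to_dataset_size(self):
        table = tf.accuracy_by_category(self._report(sep=1.0))
        assert table.n_images.sum() == 60

    def test_rows_equal_confusion_recount(self):
        report = self._report(sep=1.0)
        table = tf.accuracy_by_category(report)
        for _, row in table.iterrows():
            mask = report.predictions.label == row.category
            n = int(mask.sum())
            correct = int((report.predictions[mask].predicted == row.category).sum())
            assert row.n_images == n
            assert np.isclose(row.accuracy, correct / n)


class TestTSNE:
    def test_shape_and_determinism(self):
        X, _ = generate_feature_testset(n=40, d=10, k=2, separation=5.0, seed=0)
        a = tf.tsne_embed(X, seed=1)
        b = tf.tsne_embed(X, seed=1)
        assert a.shape == (40, 2)
        assert np.array_equal(a, b)

    def test_separated_clouds_stay_separated(self):
        X, y = generate_feature_testset(n=60, d=20, k=2, separation=40.0, seed=2)
        coords = tf.tsne_embed(X, seed=0)
        # nearest-neighbor label agreement > 0.9 on far-separated clusters
        d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
        np.fill_diagonal(d2, np.inf)
        nn = d2.argmin(axis=1)
        assert np.mean(y[nn] == y) > 0.9

    def test_too_few_samples_is_usage_error(self):
        with pytest.raises(UsageError):
            tf.tsne_embed(np.zeros((4, 3)), seed=0)
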