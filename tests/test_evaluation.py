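import math

import numpy as np
import pytest

import oracles
from protclass import (
    ConfusionCounts,
    KernelSpec,
    aggregate_report,
    auc_roc,
    balanced_sample_sets,
    compute_metrics,
    get_encoder,
    kfold_split,
    roc_curve,
    run_cv,
    run_loocv,
)
from protclass.synthetic import generate_dataset, leucine_enriched_preset, null_preset


class TestConfusionCounts:
    def test_total(self):
        assert ConfusionCounts(3, 2, 2, 1).total == 8

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 0, 0)

    def test_from_predictions(self):
        y = np.array([1, 1, 1, 1, -1, -1, -1, -1])
        p = np.array([1, 1, 1, -1, 1, 1, -1, -1])
        counts = ConfusionCounts.from_predictions(y, p)
        assert (counts.tp, counts.tn, counts.fp, counts.fn) == (3, 2, 2, 1)

    def test_addition(self):
        total = ConfusionCounts(1, 2, 3, 4) + ConfusionCounts(4, 3, 2, 1)
        assert (total.tp, total.tn, total.fp, total.fn) == (5, 5, 5, 5)


class TestComputeMetrics:
    def test_perfect_classifier(self):
        m = compute_metrics(ConfusionCounts(tp=5, tn=5, fp=0, fn=0))
        assert m["Sn"] == m["Sp"] == m["Ac"] == m["Pre"] == 1.0
        assert m["MCC"] == 1.0

    def test_hand_evaluated_fixture(self):
        # tp=3, fn=1, tn=2, fp=2
        m = compute_metrics(ConfusionCounts(tp=3, tn=2, fp=2, fn=1))
        assert m["Sn"] == pytest.approx(0.75)
        assert m["Sp"] == pytest.approx(0.5)
        assert m["Ac"] == pytest.approx(0.625)
        assert m["Pre"] == pytest.approx(0.6)
        assert m["MCC"] == pytest.approx(4 / math.sqrt(4 * 5 * 3 * 4))
        assert m["MCC"] == pytest.approx(0.2582, abs=5e-5)

    def test_zero_denominator_is_undefined_not_zero(self):
        m = compute_metrics(ConfusionCounts(tp=0, tn=4, fp=0, fn=2))
        assert math.isnan(m["Pre"])
        assert not math.isnan(m["Sn"])
        assert not math.isnan(m["Sp"])
        assert not math.isnan(m["Ac"])

    def test_class_swap_preserves_mcc_and_swaps_sn_sp(self):
        # renaming the classes swaps tp<->tn and fp<->fn
        counts = ConfusionCounts(tp=7, tn=3, fp=2, fn=5)
        flipped = ConfusionCounts(tp=3, tn=7, fp=5, fn=2)
        m, mf = compute_metrics(counts), compute_metrics(flipped)
        assert mf["MCC"] == pytest.approx(m["MCC"])
        assert mf["Sn"] == pytest.approx(m["Sp"])
        assert mf["Sp"] == pytest.approx(m["Sn"])

    def test_mcc_negates_when_predictions_inverted(self):
        counts = ConfusionCounts(tp=7, tn=3, fp=2, fn=5)
        inverted = ConfusionCounts(tp=5, tn=2, fp=3, fn=7)
        assert compute_metrics(inverted)["MCC"] == pytest.approx(
            -compute_metrics(counts)["MCC"]
        )

    def test_balanced_ac_is_mean_of_sn_sp(self):
        counts = ConfusionCounts(tp=8, fn=2, tn=6, fp=4)  # 10 pos, 10 neg
        m = compute_metrics(counts)
        assert m["Ac"] == pytest.approx((m["Sn"] + m["Sp"]) / 2)


class TestRocAuc:
    def test_perfect_ranking(self):
        scores = np.array([0.9, 0.8, 0.7, 0.2, 0.1])
        labels = np.array([1, 1, 1, -1, -1])
        assert auc_roc(scores, labels) == pytest.approx(1.0)

    def test_reversed_ranking(self):
        scores = np.array([0.1, 0.2, 0.9, 0.8])
        labels = np.array([1, 1, -1, -1])
        assert auc_roc(scores, labels) == pytest.approx(0.0)

    def test_curve_endpoints_and_monotonicity(self, rng):
        scores = rng.normal(size=40)
        labels = np.where(rng.random(40) < 0.5, 1, -1)
        if len(set(labels)) < 2:
            labels[0], labels[1] = 1, -1
        curve = roc_curve(scores, labels)
        assert curve.fpr[0] == curve.tpr[0] == 0.0
        assert curve.fpr[-1] == curve.tpr[-1] == 1.0
        assert (np.diff(curve.fpr) >= 0).all()
        assert (np.diff(curve.tpr) >= 0).all()

    def test_matches_pairwise_oracle_with_ties(self, rng):
        for trial in range(50):
            n = int(rng.integers(4, 25))
            scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
            labels = np.where(rng.random(n) < 0.5, 1, -1)
            if len(set(labels)) < 2:
                continue
            assert auc_roc(scores, labels) == pytest.approx(
                oracles.naive_auc(scores.tolist(), labels.tolist()), abs=1e-9
            )

    def test_random_scores_near_half(self, rng):
        scores = rng.normal(size=1000)
        labels = np.where(rng.random(1000) < 0.5, 1, -1)
        assert abs(auc_roc(scores, labels) - 0.5) < 0.05

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(size=60)
        labels = np.where(rng.random(60) < 0.5, 1, -1)
        labels[:2] = [1, -1]
        base = auc_roc(scores, labels)
        assert auc_roc(np.exp(scores), labels) == pytest.approx(base, abs=1e-12)
        assert auc_roc(3 * scores + 7, labels) == pytest.approx(base, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_roc(np.array([0.1, 0.2]), np.array([1, 1]))


class TestKfoldSplit:
    def test_exact_division(self):
        folds = kfold_split(100, 10, seed=0)
        assert [len(f) for f in folds] == [10] * 10

    def test_uneven_division(self):
        sizes = sorted(len(f) for f in kfold_split(103, 10, seed=0))
        assert sizes == [10] * 7 + [11] * 3

    def test_partition_property(self):
        folds = kfold_split(57, 7, seed=4)
        union = np.sort(np.concatenate(folds))
        np.testing.assert_array_equal(union, np.arange(57))

    def test_stratified_preserves_ratio(self):
        labels = np.r_[np.ones(30, dtype=int), -np.ones(30, dtype=int)]
        folds = kfold_split(60, 10, seed=1, stratified=True, labels=labels)
        for fold in folds:
            assert len(fold) == 6
            assert np.sum(labels[fold] == 1) == 3

    def test_stratified_sizes_within_one(self):
        labels = np.r_[np.ones(13, dtype=int), -np.ones(17, dtype=int)]
        folds = kfold_split(30, 7, seed=1, stratified=True, labels=labels)
        sizes = [len(f) for f in folds]
        assert max(sizes) - min(sizes) <= 1
        union = np.sort(np.concatenate(folds))
        np.testing.assert_array_equal(union, np.arange(30))
        for fold in folds:
            n_pos = np.sum(labels[fold] == 1)
            assert abs(n_pos - 13 * len(fold) / 30) <= 1

    def test_k_greater_than_n_rejected(self):
        with pytest.raises(ValueError):
            kfold_split(5, 10, seed=0)

    def test_seeded_reproducibility(self):
        a = kfold_split(40, 5, seed=9)
        b = kfold_split(40, 5, seed=9)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)


@pytest.fixture(scope="module")
def pools():
    pos, neg = null_preset(length_range=(30, 60))
    ds = generate_dataset(pos, neg, 12, 300, seed=5)
    return (
        [r for r, y in zip(ds.records, ds.labels) if y == 1],
        [r for r, y in zip(ds.records, ds.labels) if y == -1],
    )


@pytest.fixture(scope="module")
def signal_dataset():
    pos, neg = leucine_enriched_preset(length_range=(60, 120))
    return generate_dataset(pos, neg, 15, 15, seed=21)


class TestBalancedSampleSets:
    def test_each_set_balanced(self, pools):
        pos, neg = pools
        sets = balanced_sample_sets(pos, neg, n_sets=10, seed=0)
        assert len(sets) == 10
        for ds in sets:
            assert len(ds) == 24
            assert np.sum(ds.labels == 1) == 12
            assert np.sum(ds.labels == -1) == 12

    def test_all_positives_present(self, pools):
        pos, neg = pools
        for ds in balanced_sample_sets(pos, neg, n_sets=3, seed=0):
            assert {r.id for r in pos} <= set(ds.ids)

    def test_no_replacement_within_set(self, pools):
        pos, neg = pools
        for ds in balanced_sample_sets(pos, neg, n_sets=5, seed=0):
            neg_ids = [i for i, y in zip(ds.ids, ds.labels) if y == -1]
            assert len(set(neg_ids)) == len(neg_ids)

    def test_draws_differ_across_sets(self, pools):
        pos, neg = pools
        sets = balanced_sample_sets(pos, neg, n_sets=10, seed=0)
        draws = {frozenset(i for i, y in zip(d.ids, d.labels) if y == -1) for d in sets}
        assert len(draws) == 10

    def test_equal_pool_sizes_single_choice(self, pools):
        pos, _ = pools
        sets = balanced_sample_sets(pos, pos, n_sets=1, seed=0)
        assert sorted(sets[0].ids) == sorted([r.id for r in pos] * 2)

    def test_too_few_negatives(self, pools):
        pos, neg = pools
        with pytest.raises(ValueError):
            balanced_sample_sets(pos, pos[:5], n_sets=1, seed=0)

    def test_seeded_reproducibility(self, pools):
        pos, neg = pools
        a = balanced_sample_sets(pos, neg, n_sets=4, seed=3)
        b = balanced_sample_sets(pos, neg, n_sets=4, seed=3)
        assert [d.ids for d in a] == [d.ids for d in b]


class TestRunCv:
    def test_folds_reassemble_dataset(self, signal_dataset):
        folds = run_cv(signal_dataset, get_encoder("AAC"), k=5, seed=0)
        test_ids = [i for f in folds for i in f.test_ids]
        assert sorted(test_ids) == sorted(signal_dataset.ids)

    def test_no_test_instance_in_own_training_fold(self, signal_dataset):
        folds = run_cv(signal_dataset, get_encoder("AAC"), k=5, seed=0)
        for fold in folds:
            assert not set(fold.test_ids) & set(fold.train_ids)

    def test_counts_cover_fold(self, signal_dataset):
        folds = run_cv(signal_dataset, get_encoder("AAC"), k=5, seed=0)
        for fold in folds:
            assert fold.counts.total == len(fold.test_ids)

    def test_separable_dataset_perfect_folds(self):
        # extreme composition difference: trivially separable
        pos, neg = leucine_enriched_preset(length_range=(80, 120))
        from protclass import ClassGenerator
        import numpy as np
        w_pos = np.zeros(20); w_pos[:2] = 0.5
        w_neg = np.zeros(20); w_neg[-2:] = 0.5
        pos = ClassGenerator(w_pos, np.tile(w_pos, (20, 1)), (80, 120))
        neg = ClassGenerator(w_neg, np.tile(w_neg, (20, 1)), (80, 120))
        ds = generate_dataset(pos, neg, 10, 10, seed=3)
        folds = run_cv(ds, get_encoder("AAC"), KernelSpec("linear"), k=5, seed=0)
        assert all(f.metrics["Ac"] == 1.0 for f in folds)


class TestRunLoocv:
    def test_30_iterations_and_pooled_total(self):
        pos, neg = leucine_enriched_preset(length_range=(50, 90))
        ds = generate_dataset(pos, neg, 15, 15, seed=2)
        result = run_loocv(ds, get_encoder("AAC"))
        assert len(result.ids) == 30
        assert result.counts.total == 30

    def test_perfect_toy_set(self):
        from protclass import ClassGenerator
        w_pos = np.zeros(20); w_pos[0] = 1.0
        w_neg = np.zeros(20); w_neg[1] = 1.0
        pos = ClassGenerator(w_pos, np.tile(w_pos, (20, 1)), (30, 40))
        neg = ClassGenerator(w_neg, np.tile(w_neg, (20, 1)), (30, 40))
        ds = generate_dataset(pos, neg, 3, 3, seed=1)
        result = run_loocv(ds, get_encoder("AAC"), KernelSpec("linear"))
        assert result.metrics["Ac"] == 1.0

    def test_too_small_rejected(self):
        pos, neg = null_preset(length_range=(30, 40))
        ds = generate_dataset(pos, neg, 1, 1, seed=0)
        with pytest.raises(ValueError):
            run_loocv(ds, get_encoder("AAC"))


class TestAggregateReport:
    def test_constant_values(self):
        metrics = {m: 0.7 for m in ("Sn", "Sp", "Ac", "Pre", "MCC", "AUC")}
        report = aggregate_report([[metrics] * 3] * 4)
        summary = report.summary()
        assert summary["mean"].tolist() == pytest.approx([0.7] * 6)
        assert summary["sd"].tolist() == pytest.approx([0.0] * 6)
        assert report.n_cells_per_metric == 12

    def test_two_value_sd(self):
        m1 = {m: 0.8 for m in ("Sn", "Sp", "Ac", "Pre", "MCC", "AUC")}
        m2 = {m: 1.0 for m in ("Sn", "Sp", "Ac", "Pre", "MCC", "AUC")}
        summary = aggregate_report([[m1], [m2]]).summary()
        assert summary.loc["Ac", "mean"] == pytest.approx(0.9)
        assert summary.loc["Ac", "sd"] == pytest.approx(0.1414, abs=5e-4)

    def test_undefined_cells_excluded_and_counted(self):
        good = {m: 0.5 for m in ("Sn", "Sp", "Ac", "Pre", "MCC", "AUC")}
        bad = dict(good, Pre=math.nan)
        summary = aggregate_report([[good, bad]]).summary()
        assert summary.loc["Pre", "mean"] == pytest.approx(0.5)
        assert summary.loc["Pre", "n_undefined"] == 1
        assert summary.loc["Pre", "n_defined"] == 1

    def test_all_undefined_metric_raises(self):
        bad = {m: math.nan for m in ("Sn", "Sp", "Ac", "Pre", "MCC", "AUC")}
        with pytest.raises(ValueError):
            aggregate_report([[bad]]).summary()

    def test_csv_output(self, tmp_path):
        metrics = {m: 0.6 for m in ("Sn", "Sp", "Ac", "Pre", "MCC", "AUC")}
        report = aggregate_report([[metrics, metrics]])
        full, summary = tmp_path / "full.csv", tmp_path / "summary.csv"
        report.to_csv(full, summary)
        assert full.exists() and summary.exists()
        assert "Ac" in summary.read_text()
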