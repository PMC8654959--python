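"""Metric suite, ROC/AUC, fold machinery, CV / independent-test protocols."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import confusion_matrix, matthews_corrcoef, roc_auc_score

from acpcnn import (
    ConfusionCounts,
    SyntheticSpec,
    combination_sweep,
    compute_metrics,
    confusion_counts,
    cross_validate,
    evaluate_predictions,
    generate_synthetic,
    independent_test,
    preset_config,
    roc_and_auc,
    stratified_kfold,
)


def auc_concordance_oracle(y_true, scores):
    """Pairwise-concordance AUC: P(score_pos > score_neg) + 0.5 P(tie)."""
    pos = [s for s, y in zip(scores, y_true) if y == 1]
    neg = [s for s, y in zip(scores, y_true) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestConfusionCounts:
    def test_direct_count(self):
        c = confusion_counts([1, 1, 0, 0], [1, 0, 0, 1])
        assert (c.tp, c.fn, c.tn, c.fp) == (1, 1, 1, 1)

    def test_perfect_prediction(self):
        c = confusion_counts([1, 0, 1], [1, 0, 1])
        assert c.fp == 0 and c.fn == 0

    def test_all_positive_predictions(self):
        c = confusion_counts([1, 0], [1, 1])
        assert (c.tp, c.fp) == (1, 1)

    def test_length_mismatch_and_nonbinary(self):
        with pytest.raises(ValueError):
            confusion_counts([1, 0], [1])
        with pytest.raises(ValueError):
            confusion_counts([1, 2], [1, 0])


class TestComputeMetrics:
    def test_perfect_classifier(self):
        r = compute_metrics(ConfusionCounts(tp=5, tn=5, fp=0, fn=0))
        assert (r.accuracy, r.sensitivity, r.specificity, r.precision) == (
            100.0, 100.0, 100.0, 100.0,
        )
        assert r.mcc == 1.0

    def test_worked_example(self):
        """tp=3, tn=4, fp=1, fn=2: accuracy 70, sensitivity 60, specificity 80,
        precision 75, MCC = (12-2)/sqrt(4*5*5*6)."""
        r = compute_metrics(ConfusionCounts(tp=3, tn=4, fp=1, fn=2))
        assert r.accuracy == pytest.approx(70.0)
        assert r.sensitivity == pytest.approx(60.0)
        assert r.specificity == pytest.approx(80.0)
        assert r.precision == pytest.approx(75.0)
        assert r.mcc == pytest.approx(10 / np.sqrt(600), abs=1e-9)

    def test_totally_inaccurate(self):
        r = compute_metrics(ConfusionCounts(tp=0, tn=0, fp=1, fn=1))
        assert r.accuracy == 0.0 and r.mcc == -1.0

    def test_mcc_zero_denominator_convention(self):
        r = compute_metrics(ConfusionCounts(tp=2, tn=0, fp=0, fn=0))
        assert r.mcc == 0.0

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(ConfusionCounts(0, 0, 0, 0))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(2, 80))
    def test_agrees_with_sklearn_on_random_vectors(self, seed, n):
        rng = np.random.default_rng(seed)
        yt = rng.integers(0, 2, n)
        yp = rng.integers(0, 2, n)
        r = compute_metrics(confusion_counts(yt, yp))
        tn, fp, fn, tp = confusion_matrix(yt, yp, labels=[0, 1]).ravel()
        assert (r.counts.tp, r.counts.tn, r.counts.fp, r.counts.fn) == (
            tp, tn, fp, fn,
        )
        assert r.accuracy == pytest.approx(100 * (tp + tn) / n)
        denom_zero = 0 in (tp + fp, tp + fn, tn + fp, tn + fn)
        if not denom_zero:
            assert r.mcc == pytest.approx(matthews_corrcoef(yt, yp), abs=1e-9)

    def test_metric_identity_accuracy_decomposition(self, rng):
        yt = rng.integers(0, 2, 100)
        yp = rng.integers(0, 2, 100)
        r = compute_metrics(confusion_counts(yt, yp))
        P = int(np.sum(yt == 1))
        N = 100 - P
        lhs = r.accuracy / 100 * 100
        rhs = r.sensitivity / 100 * P + r.specificity / 100 * N
        assert lhs == pytest.approx(rhs)


class TestROC:
    def test_perfect_separation(self):
        *_, auc = roc_and_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert auc == pytest.approx(1.0)

    def test_constant_scores_give_half(self):
        *_, auc = roc_and_auc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5])
        assert auc == pytest.approx(0.5)

    def test_toy_four_records(self):
        *_, auc = roc_and_auc([1, 1, 0, 0], [0.9, 0.4, 0.6, 0.1])
        assert auc == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_and_auc([1, 1], [0.5, 0.6])

    def test_scores_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            roc_and_auc([0, 1], [0.5, 1.2])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(4, 200))
    def test_threshold_sweep_equals_concordance_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        yt = np.concatenate([[0, 1], rng.integers(0, 2, n - 2)])
        # quantize so ties actually occur
        sc = np.round(rng.random(n), 1)
        *_, auc = roc_and_auc(yt, sc)
        assert auc == pytest.approx(auc_concordance_oracle(yt, sc), abs=1e-9)
        assert auc == pytest.approx(roc_auc_score(yt, sc), abs=1e-9)


class TestStratifiedKFold:
    def test_benchmark_sized_split(self):
        """376 positives + 364 negatives in 5 folds: 148 each, 75-76 positives."""
        y = np.array([1] * 376 + [0] * 364)
        split = stratified_kfold(y, n_folds=5, seed=0)
        for fold in range(5):
            _, test = split.fold_indices(fold)
            assert len(test) == 148
            assert int(np.sum(y[test])) in (75, 76)

    def test_exact_divisibility(self):
        y = np.array([1] * 5 + [0] * 5)
        split = stratified_kfold(y, n_folds=5, seed=1)
        for fold in range(5):
            _, test = split.fold_indices(fold)
            assert len(test) == 2 and int(np.sum(y[test])) == 1

    def test_seeded_reproducibility(self):
        y = np.array([1] * 30 + [0] * 25)
        a = stratified_kfold(y, 5, seed=9).assignments
        b = stratified_kfold(y, 5, seed=9).assignments
        assert np.array_equal(a, b)
        c = stratified_kfold(y, 5, seed=10).assignments
        assert not np.array_equal(a, c)

    def test_class_smaller_than_folds_rejected(self):
        with pytest.raises(ValueError, match="fewer"):
            stratified_kfold(np.array([1, 1, 0, 0, 0, 0, 0]), n_folds=3)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        n_pos=st.integers(5, 60),
        n_neg=st.integers(5, 60),
        n_folds=st.integers(2, 5),
        seed=st.integers(0, 1000),
    )
    def test_partition_and_stratification_invariants(self, n_pos, n_neg, n_folds, seed):
        y = np.array([1] * n_pos + [0] * n_neg)
        split = stratified_kfold(y, n_folds=n_folds, seed=seed)
        assert np.all(split.assignments >= 0)  # exhaustive
        for cls in (0, 1):
            counts = [
                int(np.sum((split.assignments == f) & (y == cls)))
                for f in range(n_folds)
            ]
            assert max(counts) - min(counts) <= 1


@pytest.fixture(scope="module")
def small_cv_setup():
    """Small, fast CV scenario shared by the protocol tests."""
    ds = generate_synthetic(
        SyntheticSpec(n_pos=60, n_neg=60, signal_prob=1.0, seed=3)
    )
    cfg = preset_config("acp740", combination=("BPF",), max_epochs=30, patience=30)
    return ds, cfg


class TestCrossValidate:
    def test_reports_consistent_with_stored_predictions(self, small_cv_setup, encoder):
        ds, cfg = small_cv_setup
        res = cross_validate(ds, cfg, "C1", n_folds=3, seed=5, encoder=encoder)
        assert len(res.fold_reports) == 3
        for report, (yt, yp, sc) in zip(res.fold_reports, res.fold_predictions):
            again = evaluate_predictions(yt, yp, sc)
            assert report.as_dict() == again.as_dict()

    def test_folds_match_stratified_kfold(self, small_cv_setup, encoder):
        ds, cfg = small_cv_setup
        res = cross_validate(ds, cfg, "C1", n_folds=3, seed=5, encoder=encoder)
        expected = stratified_kfold(ds.labels, 3, seed=5)
        assert np.array_equal(res.split.assignments, expected.assignments)

    def test_mean_std_recomputed_from_folds(self, small_cv_setup, encoder):
        ds, cfg = small_cv_setup
        res = cross_validate(ds, cfg, "C1", n_folds=3, seed=5, encoder=encoder)
        accs = [r.accuracy for r in res.fold_reports]
        assert res.mean["accuracy"] == pytest.approx(np.mean(accs), abs=1e-9)
        assert res.std["accuracy"] == pytest.approx(np.std(accs), abs=1e-9)

    def test_report_frame_has_mean_and_std_rows(self, small_cv_setup, encoder):
        ds, cfg = small_cv_setup
        res = cross_validate(ds, cfg, "C1", n_folds=3, seed=5, encoder=encoder)
        frame = res.to_frame()
        assert list(frame.index)[-2:] == ["mean", "std"]
        assert "accuracy" in frame.columns


class TestIndependentTest:
    def test_strong_signal_recovery_and_repeatable_scoring(self, encoder):
        train = generate_synthetic(
            SyntheticSpec(n_pos=250, n_neg=250, signal_prob=1.0, seed=21)
        )
        test = generate_synthetic(
            SyntheticSpec(n_pos=82, n_neg=82, signal_prob=1.0, seed=22)
        )
        test = type(test)(
            [type(r)(f"t_{r.id}", r.sequence, r.label) for r in test], name="test"
        )
        cfg = preset_config("acp740", combination=("BPF",), seed=1)
        report, model = independent_test(train, test, cfg, "C1", encoder=encoder)
        assert report.accuracy >= 90.0  # strong plantable signal
        # scoring the untouched test set again gives the identical report
        stacks, y = encoder.encode_dataset(test, ("BPF",))
        probs = model.predict_proba(stacks)
        again = evaluate_predictions(
            y, (probs[:, 1] > 0.5).astype(int), probs[:, 1]
        )
        assert again.as_dict() == report.as_dict()

    def test_shared_ids_warn_of_leakage(self, encoder, small_cv_setup):
        ds, cfg = small_cv_setup
        with pytest.warns(UserWarning, match="leakage"):
            independent_test(ds, ds[[0, 1, 60, 61]], cfg, "C1", encoder=encoder)


class TestCombinationSweep:
    def test_seven_rows_with_expected_group_counts(self, encoder):
        ds = generate_synthetic(
            SyntheticSpec(n_pos=25, n_neg=25, signal_prob=1.0, seed=13)
        )
        cfg = preset_config("acp740", max_epochs=8, patience=8)
        table = combination_sweep(ds, cfg, n_folds=2, seed=2, encoder=encoder)
        assert list(table.index) == ["C1", "C2", "C3", "C4", "C5", "C6", "C7"]
        assert table.loc["C5", "n_groups"] == 2
        assert table.loc["C7", "n_groups"] == 3
        assert {"accuracy", "accuracy_std", "mcc"} <= set(table.columns)
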