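import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermostage.evaluate import (ConfusionCounts, SplitSpec,
                                  UndefinedMetricError, auc, binary_metrics,
                                  confusion_from_predictions,
                                  evaluate_predictions, roc_auc, roc_curve,
                                  split_indices, stratified_split)
from thermostage.io import DatasetManifest


def make_manifest(counts):
    entries = [(f"im_{s}_{i}.png", s) for s, n in counts.items() for i in range(n)]
    return DatasetManifest(entries=entries, name="t")


def mann_whitney_auc(scores, labels):
    """Brute-force pair-counting oracle (ties count one half)."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    pos, neg = s[y == 1], s[y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestStratifiedSplit:
    def test_reference_counts_reproduce_70_30_table(self):
        m = make_manifest({0: 27, 1: 93, 2: 61, 3: 31})
        train, test = stratified_split(m, SplitSpec(train_fraction=0.7, seed=17))
        assert train.class_counts() == {0: 19, 1: 65, 2: 43, 3: 22}
        assert test.class_counts() == {0: 8, 1: 28, 2: 18, 3: 9}
        assert (len(train), len(test)) == (149, 63)

    def test_single_stage_split(self):
        m = make_manifest({0: 10})
        train, test = stratified_split(m, SplitSpec(train_fraction=0.7))
        assert (len(train), len(test)) == (7, 3)

    def test_balanced_subsamples_to_minimum_before_split(self):
        m = make_manifest({0: 27, 1: 93, 2: 61, 3: 31})
        train, test = stratified_split(m, SplitSpec(balanced=True, seed=17))
        for s in range(4):
            assert train.class_counts()[s] + test.class_counts()[s] == 27
            assert train.class_counts()[s] == 19

    def test_every_stage_kept_in_test(self):
        # fraction high enough to swallow a tiny stage entirely
        m = make_manifest({0: 2, 1: 50})
        train, test = stratified_split(m, SplitSpec(train_fraction=0.9))
        assert test.class_counts()[0] >= 1

    def test_deterministic_given_seed_and_disjoint(self):
        y = np.repeat([0, 1, 2, 3], [27, 93, 61, 31])
        tr1, te1 = split_indices(y, SplitSpec(seed=5))
        tr2, te2 = split_indices(y, SplitSpec(seed=5))
        np.testing.assert_array_equal(tr1, tr2)
        assert set(tr1).isdisjoint(te1)
        assert len(set(tr1) | set(te1)) == len(y)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            SplitSpec(train_fraction=1.0)


# Integer confusion counts reconstructed from the published per-stage
# sensitivity/specificity and test-set sizes (8/28/18/9 positives out of 63).
RECONSTRUCTED_TABLE = {
    0: ConfusionCounts(tp=1, fn=7, tn=53, fp=2),
    1: ConfusionCounts(tp=25, fn=3, tn=23, fp=12),
    2: ConfusionCounts(tp=10, fn=8, tn=36, fp=9),
    3: ConfusionCounts(tp=3, fn=6, tn=53, fp=1),
}

PRINTED_ROWS = {  # stage: (TPR, TNR, PPV, F, class_accuracy)
    0: (0.125, 0.963, 0.333, 0.181, 0.857),
    1: (0.892, 0.657, 0.675, 0.769, 0.761),
    2: (0.555, 0.800, 0.526, 0.540, 0.730),
    3: (0.333, 0.981, 0.750, 0.461, 0.888),
}


class TestBinaryMetrics:
    @pytest.mark.parametrize("stage", [0, 1, 2, 3])
    def test_reconstructed_counts_reproduce_printed_rates(self, stage):
        row = binary_metrics(RECONSTRUCTED_TABLE[stage], stage=stage)
        tpr, tnr, ppv, f, acc = PRINTED_ROWS[stage]
        assert row["TPR"] == pytest.approx(tpr, abs=1e-3)
        assert row["TNR"] == pytest.approx(tnr, abs=1e-3)
        assert row["PPV"] == pytest.approx(ppv, abs=1e-3)
        assert row["F_score"] == pytest.approx(f, abs=1e-3)
        assert row["class_accuracy"] == pytest.approx(acc, abs=1e-3)

    def test_rate_complements_sum_to_one(self):
        row = binary_metrics(ConfusionCounts(tp=25, fn=3, tn=23, fp=12))
        assert row["TPR"] + row["FNR"] == pytest.approx(1.0)
        assert row["TNR"] + row["FPR"] == pytest.approx(1.0)

    def test_degenerate_all_negative_predictions(self):
        row = binary_metrics(ConfusionCounts(tp=0, fn=5, tn=5, fp=0))
        assert row["TPR"] == 0.0 and row["TNR"] == 1.0 and row["F_score"] == 0.0

    def test_perfect_classifier_all_ones(self):
        row = binary_metrics(ConfusionCounts(tp=7, fn=0, tn=11, fp=0))
        for key in ("TPR", "TNR", "PPV", "F_score", "class_accuracy"):
            assert row[key] == 1.0

    def test_empty_class_raises_named_error(self):
        with pytest.raises(UndefinedMetricError, match="stage 2"):
            binary_metrics(ConfusionCounts(tp=0, fn=0, tn=5, fp=1), stage=2)

    def test_f_between_ppv_and_tpr(self):
        row = binary_metrics(ConfusionCounts(tp=25, fn=3, tn=23, fp=12))
        assert min(row["PPV"], row["TPR"]) <= row["F_score"] <= max(row["PPV"], row["TPR"])


class TestROC:
    def test_perfect_separation_passes_through_corner(self):
        fpr, tpr = roc_curve([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert any((f == 0.0 and t == 1.0) for f, t in zip(fpr, tpr))
        assert auc(fpr, tpr) == 1.0

    def test_three_of_four_pairs_ordered_gives_075(self):
        assert roc_auc([0.9, 0.3, 0.6, 0.1], [1, 1, 0, 0]) == pytest.approx(0.75)

    def test_identical_scores_give_diagonal(self):
        fpr, tpr = roc_curve([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0])
        np.testing.assert_allclose(fpr, tpr)  # every point on the diagonal
        assert auc(fpr, tpr) == pytest.approx(0.5)

    def test_curve_monotone_and_endpoints(self):
        rng = np.random.default_rng(1)
        s = rng.random(50)
        y = rng.integers(0, 2, 50)
        if len(np.unique(y)) < 2:
            y[0], y[1] = 0, 1
        fpr, tpr = roc_curve(s, y)
        assert fpr[0] == tpr[0] == 0.0 and fpr[-1] == tpr[-1] == 1.0
        assert np.all(np.diff(fpr) >= 0) and np.all(np.diff(tpr) >= 0)

    def test_score_negation_mirrors_curve(self):
        # with the predict-positive-at-or-above-threshold convention,
        # negating scores maps the point set (FPR, TPR) -> (1-FPR, 1-TPR);
        # identity confirmed by brute-force threshold enumeration
        rng = np.random.default_rng(2)
        s = rng.random(20)
        y = np.r_[np.ones(10, int), np.zeros(10, int)]
        pts = {(round(f, 12), round(t, 12)) for f, t in zip(*roc_curve(s, y))}
        mirrored = {(round(1 - f, 12), round(1 - t, 12))
                    for f, t in zip(*roc_curve(-s, y))}
        assert pts == mirrored
        assert roc_auc(-s, y) == pytest.approx(1 - roc_auc(s, y))

    def test_one_class_raises(self):
        with pytest.raises(UndefinedMetricError):
            roc_curve([0.1, 0.2], [1, 1])

    @settings(max_examples=200, deadline=None)
    @given(st.data())
    def test_trapezoid_auc_equals_mann_whitney(self, data):
        n = data.draw(st.integers(4, 50))
        y = np.array(data.draw(
            st.lists(st.integers(0, 1), min_size=n, max_size=n)))
        if y.sum() == 0 or y.sum() == n:
            y[0], y[1] = 0, 1
        # coarse grid encourages ties
        s = np.array(data.draw(st.lists(
            st.integers(0, 10), min_size=n, max_size=n))) / 10.0
        assert roc_auc(s, y) == pytest.approx(mann_whitney_auc(s, y), abs=1e-12)

    def test_random_labels_auc_near_half(self):
        rng = np.random.default_rng(3)
        s = rng.random(2000)
        y = rng.integers(0, 2, 2000)
        n1, n0 = y.sum(), (1 - y).sum()
        se = np.sqrt((n0 + n1 + 1) / (12 * n0 * n1))
        assert roc_auc(s, y) == pytest.approx(0.5, abs=3 * se)


class TestEvaluatePredictions:
    def test_reference_accuracy_average(self):
        # class accuracies 54/63, 48/63, 46/63, 56/63 average to 0.80952
        accs = [54 / 63, 48 / 63, 46 / 63, 56 / 63]
        assert np.mean(accs) == pytest.approx(0.80952, abs=1e-5)

    def test_perfect_predictions(self):
        y = np.repeat([0, 1, 2, 3], [8, 28, 18, 9])
        report = evaluate_predictions(y, y)
        assert report.average["class_accuracy"] == pytest.approx(1.0)
        assert report.average["TPR"] == pytest.approx(1.0)

    def test_constant_majority_predictor_confusion(self):
        y = np.repeat([0, 1, 2, 3], [8, 28, 18, 9])
        pred = np.ones_like(y)
        report = evaluate_predictions(y, pred)
        row1 = report.table.loc["Stage 1 (mild)"]
        assert row1["TPR"] == 1.0 and row1["TNR"] == 0.0
        c = confusion_from_predictions(y, pred, 1)
        assert (c.tp, c.fn, c.tn, c.fp) == (28, 0, 0, 35)

    def test_report_internal_consistency(self):
        rng = np.random.default_rng(4)
        y = np.repeat([0, 1, 2, 3], [8, 28, 18, 9])
        pred = rng.integers(0, 4, size=y.size)
        scores = rng.random((y.size, 4))
        report = evaluate_predictions(y, pred, scores)
        for s in range(4):
            row = report.table.iloc[s]
            assert row["TPR"] + row["FNR"] == pytest.approx(1.0)
            assert row["TNR"] + row["FPR"] == pytest.approx(1.0)
            c = report.confusions[s]
            assert row["class_accuracy"] == pytest.approx((c.tp + c.tn) / 63)
            assert c.positives == row["n_test"]
        avg = report.average
        assert avg["class_accuracy"] == pytest.approx(
            report.table["class_accuracy"].iloc[:4].mean())

    def test_absent_stage_excluded_from_averages(self):
        y = np.repeat([0, 1, 2], [8, 28, 18])
        pred = np.zeros_like(y)
        report = evaluate_predictions(y, pred)
        assert len(report.table) == 4  # 3 stages + Average
        assert "Stage 3 (severe)" not in report.table.index

    def test_summary_and_json_render(self, tmp_path):
        y = np.repeat([0, 1, 2, 3], [8, 28, 18, 9])
        report = evaluate_predictions(y, y)
        text = report.summary()
        assert "Average" in text and "class accuracy" in text
        js = report.to_json(tmp_path / "r.json")
        assert "Stage 1 (mild)" in js
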