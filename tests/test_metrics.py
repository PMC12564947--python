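"""Evaluation metrics against enumeration oracles, bootstrap, paired tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from boluseg.metrics import (
    ConfusionCounts,
    accuracy,
    bootstrap_mean_ci,
    confusion,
    dsc,
    evaluate_set,
    frame_metrics,
    iou,
    paired_ttest,
    sensitivity,
    specificity,
)


def brute_confusion(pred, gt):
    tp = fp = fn = tn = 0
    for p, g in zip(pred.ravel(), gt.ravel()):
        if p and g:
            tp += 1
        elif p and not g:
            fp += 1
        elif not p and g:
            fn += 1
        else:
            tn += 1
    return tp, fp, fn, tn


class TestConfusion:
    def test_perfect_prediction_has_no_errors(self, rng):
        gt = rng.random((16, 16)) > 0.5
        c = confusion(gt, gt)
        assert c.fp == 0 and c.fn == 0
        assert c.tp + c.tn == gt.size

    def test_inverted_prediction_has_no_hits(self, rng):
        gt = rng.random((16, 16)) > 0.5
        c = confusion(~gt, gt)
        assert c.tp == 0 and c.tn == 0

    def test_matches_enumeration_oracle(self, rng):
        pred = rng.random((16, 16)) > 0.6
        gt = rng.random((16, 16)) > 0.4
        c = confusion(pred, gt)
        assert (c.tp, c.fp, c.fn, c.tn) == brute_confusion(pred, gt)

    def test_roi_restricts_evaluation(self, rng):
        pred = rng.random((16, 16)) > 0.5
        gt = rng.random((16, 16)) > 0.5
        roi = np.zeros((16, 16), dtype=bool)
        roi[4:12, 4:12] = True
        c = confusion(pred, gt, roi)
        assert c.total == 64

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion(np.zeros((4, 4), bool), np.zeros((4, 5), bool))


class TestMetricFormulas:
    def test_worked_example(self):
        c = ConfusionCounts(tp=6, fp=2, fn=2, tn=90)
        assert iou(c) == pytest.approx(0.6)
        assert dsc(c) == pytest.approx(0.75)
        assert accuracy(c) == pytest.approx(0.96)
        assert sensitivity(c) == pytest.approx(0.75)
        assert specificity(c) == pytest.approx(90 / 92)

    def test_perfect_prediction_scores_one_everywhere(self):
        c = ConfusionCounts(tp=10, fp=0, fn=0, tn=90)
        assert all(v == 1.0 for v in frame_metrics(c).values())

    def test_empty_pred_and_gt_degenerate_case(self):
        c = ConfusionCounts(tp=0, fp=0, fn=0, tn=100)
        assert np.isnan(iou(c)) and np.isnan(dsc(c)) and np.isnan(sensitivity(c))
        assert accuracy(c) == 1.0

    @settings(deadline=None, max_examples=50)
    @given(
        tp=st.integers(0, 50), fp=st.integers(0, 50), fn=st.integers(0, 50), tn=st.integers(0, 50)
    )
    def test_bounds_and_dice_iou_identity(self, tp, fp, fn, tn):
        c = ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)
        for v in frame_metrics(c).values():
            assert np.isnan(v) or 0.0 <= v <= 1.0
        i, d = iou(c), dsc(c)
        if not (np.isnan(i) or np.isnan(d)):
            assert d == pytest.approx(2 * i / (1 + i), abs=1e-12)

    def test_sensitivity_specificity_ignore_opposite_class(self):
        # adding true negatives never moves sensitivity; true positives never
        # move specificity
        base = ConfusionCounts(tp=5, fp=3, fn=2, tn=10)
        more_tn = ConfusionCounts(tp=5, fp=3, fn=2, tn=500)
        more_tp = ConfusionCounts(tp=500, fp=3, fn=2, tn=10)
        assert sensitivity(base) == sensitivity(more_tn)
        assert specificity(base) == specificity(more_tp)


class TestBootstrap:
    def test_constant_vector_collapses(self):
        mean, lo, hi = bootstrap_mean_ci(np.full(20, 0.7), seed=0)
        assert mean == lo == hi
        assert mean == pytest.approx(0.7, rel=1e-12)

    def test_same_seed_is_deterministic(self, rng):
        vals = rng.random(30)
        assert bootstrap_mean_ci(vals, seed=3) == bootstrap_mean_ci(vals, seed=3)

    def test_balanced_binary_ci_brackets_half(self):
        vals = np.array([0.0] * 50 + [1.0] * 50)
        mean, lo, hi = bootstrap_mean_ci(vals, n_resamples=1000, seed=1)
        assert mean == 0.5
        assert lo < 0.5 < hi
        assert abs((0.5 - lo) - (hi - 0.5)) < 0.05  # approximately symmetric

    def test_interval_shrinks_with_sample_size(self):
        rng = np.random.default_rng(5)
        small = rng.normal(0, 1, 20)
        big = rng.normal(0, 1, 200)
        _, lo_s, hi_s = bootstrap_mean_ci(small, seed=2)
        _, lo_b, hi_b = bootstrap_mean_ci(big, seed=2)
        assert (hi_b - lo_b) < (hi_s - lo_s)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_mean_ci([])


class TestPairedTTest:
    def test_identical_samples_reported_as_zero_variance(self):
        res = paired_ttest([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert res.zero_variance and np.isnan(res.statistic)

    def test_constant_shift_is_zero_variance_until_jittered(self):
        rng = np.random.default_rng(8)
        b = rng.integers(0, 1024, 10) / 1024.0  # dyadic values: +0.5 is exact
        assert paired_ttest(b + 0.5, b).zero_variance
        jitter = rng.normal(0, 1e-4, 10)
        with np.errstate(all="ignore"):
            res = paired_ttest(b + 0.5 + jitter, b)
        assert not res.zero_variance and res.pvalue < 0.05

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(9)
        a, b = rng.random(25), rng.random(25)
        d = a - b
        t_formula = d.mean() / (d.std(ddof=1) / np.sqrt(d.size))
        res = paired_ttest(a, b)
        assert res.statistic == pytest.approx(t_formula, abs=1e-10)


class TestEvaluateSet:
    def test_all_perfect_frames(self, rng):
        gts = [rng.random((8, 8)) > 0.5 for _ in range(5)]
        report = evaluate_set(gts, gts, seed=0)
        row = report.summary.loc["iou"]
        assert row["mean"] == row["ci_lo"] == row["ci_hi"] == 1.0
        assert report.n_frames == 5

    def test_single_frame_ci_degenerates_to_its_value(self, rng):
        gt = [rng.random((8, 8)) > 0.5]
        pred = [gt[0].copy()]
        pred[0][0, 0] = ~pred[0][0, 0]
        report = evaluate_set(pred, gt, seed=0)
        row = report.summary.loc["accuracy"]
        assert row["mean"] == row["ci_lo"] == row["ci_hi"]

    def test_aggregate_matches_per_frame_average(self, rng):
        preds = [rng.random((12, 12)) > 0.6 for _ in range(10)]
        gts = [rng.random((12, 12)) > 0.5 for _ in range(10)]
        report = evaluate_set(preds, gts, seed=0)
        vals = report.per_frame["iou"].dropna()
        assert report.summary.loc["iou", "mean"] == pytest.approx(vals.mean(), rel=1e-12)
        assert report.summary.loc["iou", "n_defined"] == len(vals)

    def test_misaligned_lists_rejected(self):
        with pytest.raises(ValueError):
            evaluate_set([np.zeros((4, 4), bool)], [])
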