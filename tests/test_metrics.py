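"""ROC-AUC against a brute-force oracle; pooling; threshold metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from latentaug import (
    ValidationError,
    build_report,
    pooled_auc,
    roc_auc,
    summarize_folds,
    threshold_metrics,
)


def brute_force_auc(labels, scores):
    """Exhaustive pairwise counting: wins + half-ties over all pos-neg pairs."""
    pos = [s for y, s in zip(labels, scores) if y == 1]
    neg = [s for y, s in zip(labels, scores) if y == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_complete_tie(self):
        assert roc_auc([0, 1], [0.5, 0.5]) == 0.5

    def test_hand_counted_example(self):
        # pos-neg pairs: (0.3 vs 0.4) loss, (0.3 vs 0.2) win,
        #                (0.8 vs 0.4) win,  (0.8 vs 0.2) win ... U/(2*2)
        labels, scores = [0, 1, 0, 1], [0.4, 0.3, 0.2, 0.8]
        assert roc_auc(labels, scores) == brute_force_auc(labels, scores)
        assert roc_auc(labels, scores) == pytest.approx(3 / 4)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_auc([1, 1], [0.1, 0.2])

    @settings(max_examples=500, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 50))
    def test_matches_brute_force_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        labels = np.zeros(n, dtype=int)
        labels[: rng.integers(1, n)] = 1
        rng.shuffle(labels)
        if labels.sum() in (0, n):
            labels[0] = 1 - labels[0]
        # quantized scores force ties
        scores = np.round(rng.random(n), 1)
        assert roc_auc(labels, scores) == pytest.approx(
            brute_force_auc(labels, scores), abs=1e-12
        )

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 2, 20)
        if labels.sum() in (0, 20):
            labels[0] = 1 - labels[0]
        scores = rng.random(20)
        a = roc_auc(labels, scores)
        assert roc_auc(labels, np.exp(3 * scores)) == pytest.approx(a)
        assert roc_auc(labels, 1 / (1 + np.exp(-scores))) == pytest.approx(a)

    def test_complement_identity_for_tie_free_scores(self):
        rng = np.random.default_rng(5)
        labels = np.array([0, 1] * 10)
        scores = rng.permutation(20) / 20.0
        assert roc_auc(labels, scores) + roc_auc(labels, -scores) == pytest.approx(1.0)


class TestPooledAuc:
    def test_single_fold_equals_fold_auc(self):
        labels, scores = [0, 1, 0, 1], [0.2, 0.9, 0.4, 0.6]
        assert pooled_auc([(labels, scores)]) == roc_auc(labels, scores)

    def test_duplicated_folds_invariant(self):
        fold = ([0, 1, 0, 1], [0.2, 0.9, 0.4, 0.6])
        assert pooled_auc([fold, fold]) == pooled_auc([fold])

    def test_pooling_differs_from_averaging(self):
        """Both folds separate perfectly (AUC 1) but on miscalibrated score
        ranges, so pooling the raw scores yields 7/9, not the mean of 1."""
        fold_a = ([0, 0, 1, 1], [0.1, 0.2, 0.3, 0.4])  # AUC 1.0, low range
        fold_b = ([0, 1], [0.5, 0.6])  # AUC 1.0, high range
        assert roc_auc(*fold_a) == 1.0 and roc_auc(*fold_b) == 1.0
        assert pooled_auc([fold_a, fold_b]) == pytest.approx(7 / 9)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            pooled_auc([])


class TestThresholdMetrics:
    def test_perfect_scores(self):
        m = threshold_metrics([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9], 0.5)
        assert m["accuracy"] == 1.0 and m["recall"] == 1.0 and m["specificity"] == 1.0

    def test_direct_count_example(self):
        m = threshold_metrics([1, 1, 0, 0], [0.6, 0.4, 0.6, 0.4], 0.5)
        assert m["confusion"] == (1, 1, 1, 1)  # TN, FP, FN, TP
        assert m["accuracy"] == 0.5
        assert m["recall"] == 0.5
        assert m["specificity"] == 0.5

    def test_all_negative_labels(self):
        m = threshold_metrics([0, 0, 0], [0.1, 0.6, 0.2], 0.5)
        assert m["recall"] is None
        assert m["specificity"] == pytest.approx(2 / 3)

    def test_confusion_sums_to_n(self):
        rng = np.random.default_rng(3)
        y, s = rng.integers(0, 2, 37), rng.random(37)
        m = threshold_metrics(y, s, 0.5)
        assert sum(m["confusion"]) == 37
        assert all(c >= 0 for c in m["confusion"])


class TestSummarize:
    def test_mean_of_two(self):
        out = summarize_folds([{"auc": 0.6}, {"auc": 0.8}])
        assert out["auc"]["mean"] == pytest.approx(0.7)

    def test_identical_folds_zero_sd(self):
        out = summarize_folds([{"accuracy": 0.5}] * 4)
        assert out["accuracy"]["sd"] == 0.0

    def test_sample_sd_formula(self):
        vals = [0.60, 0.60, 0.62, 0.64, 0.64]
        out = summarize_folds([{"accuracy": v} for v in vals])
        assert out["accuracy"]["mean"] == pytest.approx(0.62)
        assert out["accuracy"]["sd"] == pytest.approx(np.std(vals, ddof=1))
        lo, hi = out["accuracy"]["interval"]
        assert lo == pytest.approx(0.62 - out["accuracy"]["sd"])
        assert hi == pytest.approx(0.62 + out["accuracy"]["sd"])


def test_build_report_end_to_end():
    rng = np.random.default_rng(0)
    preds = [
        {
            "record_id": f"r{i}",
            "patient_id": f"p{i}",
            "fold": i % 2,
            "label": int(i % 2 == 0 or i % 3 == 0),
            "score": float(rng.random()),
        }
        for i in range(24)
    ]
    rep = build_report(preds)
    assert 0.0 <= rep.pooled_auc <= 1.0
    assert len(rep.per_fold) == 2
    for fold in rep.per_fold:
        n_fold = sum(1 for p in preds if p["fold"] == fold["fold"])
        assert sum(fold["confusion"]) == n_fold
    text = rep.confusion_text()
    assert "TN=" in text and "TP=" in text
    payload = rep.to_json()
    assert '"pooled_auc"' in payload
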