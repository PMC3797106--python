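import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from breakscan.classifier import (
    RiskClass,
    classify,
    contingency_stats,
    roc_auc,
    youden_threshold,
)


def brute_force_youden(counts, labels):
    """Best sens+spec over every integer cut-off (strict > rule)."""
    counts = np.asarray(counts)
    labels = np.asarray(labels)
    pos, neg = counts[labels == 1], counts[labels == 0]
    best = -np.inf
    for t in range(int(counts.min()) - 1, int(counts.max()) + 1):
        j = (pos > t).mean() + (neg <= t).mean()
        best = max(best, j)
    return best


def pairwise_auc(counts, labels):
    """O(n^2) rank-statistic oracle: P(pos > neg) + 1/2 P(tie)."""
    counts = np.asarray(counts, dtype=float)
    pos = counts[np.asarray(labels) == 1]
    neg = counts[np.asarray(labels) == 0]
    wins = sum((p > neg).sum() + 0.5 * (p == neg).sum() for p in pos)
    return wins / (len(pos) * len(neg))


class TestClassify:
    @pytest.mark.parametrize(
        "count,expected",
        [(40, RiskClass.HIGH), (35, RiskClass.HIGH), (34, RiskClass.LOW), (0, RiskClass.LOW)],
    )
    def test_strict_cutoff_at_34(self, count, expected):
        assert classify(count) == expected

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            classify(-1)


class TestContingencyStats:
    def test_reference_table_sensitivity_specificity(self):
        # 74/5 low/high in the good group, 13/17 in the poor group
        res = contingency_stats(74, 5, 13, 17)
        assert res["specificity"] == pytest.approx(74 / 79)
        assert res["sensitivity"] == pytest.approx(17 / 30)
        assert round(res["specificity"], 2) == 0.94
        assert round(res["sensitivity"], 2) == 0.57

    def test_reference_table_wald_intervals(self):
        res = contingency_stats(74, 5, 13, 17)
        lo, hi = res["sensitivity_ci"]
        assert (round(lo * 100), round(hi * 100)) == (39, 74)
        lo, hi = res["specificity_ci"]
        assert (round(lo * 100), round(hi * 100)) == (88, 99)

    def test_reference_table_all_percentages(self):
        res = contingency_stats(74, 5, 13, 17)
        gl, gh, pl, ph = res["table"]
        pct = [100 * gl / 79, 100 * gh / 79, 100 * pl / 30, 100 * ph / 30]
        assert [round(p) for p in pct] == [94, 6, 43, 57]

    def test_perfect_table(self):
        res = contingency_stats(10, 0, 0, 10)
        assert res["sensitivity"] == 1.0 and res["specificity"] == 1.0
        assert res["sensitivity_ci"] == (1.0, 1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            contingency_stats(0, 0, 13, 17)


class TestRocAuc:
    def test_separable_data(self):
        auc, ci = roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert auc == 1.0
        assert 0.0 <= ci[0] <= 1.0 == ci[1]

    def test_matches_pairwise_oracle_and_sklearn(self, rng):
        counts = rng.integers(0, 60, 100)
        labels = rng.integers(0, 2, 100)
        labels[:2] = [0, 1]  # both classes present
        auc, _ = roc_auc(counts, labels)
        assert auc == pytest.approx(pairwise_auc(counts, labels), abs=1e-12)
        from sklearn.metrics import roc_auc_score

        assert auc == pytest.approx(roc_auc_score(labels, counts), abs=1e-12)

    def test_label_swap_symmetry(self, rng):
        counts = rng.integers(0, 40, 60)
        labels = rng.integers(0, 2, 60)
        labels[:2] = [0, 1]
        auc, _ = roc_auc(counts, labels)
        auc_swapped, _ = roc_auc(counts, 1 - labels)
        assert auc_swapped == pytest.approx(1.0 - auc, abs=1e-12)

    def test_bootstrap_ci_close_to_delong(self, rng):
        counts = np.concatenate([rng.normal(10, 4, 80), rng.normal(20, 4, 40)])
        labels = np.array([0] * 80 + [1] * 40)
        auc, ci_d = roc_auc(counts, labels, ci_method="delong")
        _, ci_b = roc_auc(counts, labels, ci_method="bootstrap", seed=1)
        assert ci_d[0] < auc < ci_d[1]
        assert abs(ci_d[0] - ci_b[0]) < 0.05 and abs(ci_d[1] - ci_b[1]) < 0.05

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([1, 2, 3], [1, 1, 1])


class TestYoudenThreshold:
    def test_separable_groups_pick_smallest_tie(self):
        model = youden_threshold([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert model.threshold == 3
        assert model.sensitivity == 1.0 and model.specificity == 1.0
        assert model.auc == 1.0

    def test_attains_brute_force_optimum(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            counts = rng.integers(0, 80, 200)
            labels = (rng.random(200) < 0.3 + 0.4 * (counts > 30)).astype(int)
            if labels.min() == labels.max():
                continue
            model = youden_threshold(counts, labels)
            best = brute_force_youden(counts, labels)
            assert model.sensitivity + model.specificity == pytest.approx(best, abs=1e-12)

    def test_stored_j_dominates_every_other_cutoff(self, rng):
        counts = rng.integers(0, 50, 150)
        labels = (rng.random(150) < 0.2 + 0.5 * (counts > 25)).astype(int)
        labels[:2] = [0, 1]
        model = youden_threshold(counts, labels)
        pos, neg = counts[labels == 1], counts[labels == 0]
        for t in range(-1, 51):
            j_t = (pos > t).mean() + (neg <= t).mean() - 1.0
            assert model.youden_j >= j_t - 1e-12

    def test_model_consistent_with_stored_table(self, rng):
        counts = rng.integers(0, 60, 120)
        labels = (counts + rng.normal(0, 10, 120) > 30).astype(int)
        labels[:2] = [0, 1]
        model = youden_threshold(counts, labels)
        gl, gh, pl, ph = model.table
        assert model.specificity == pytest.approx(gl / (gl + gh))
        assert model.sensitivity == pytest.approx(ph / (pl + ph))
        assert model.classify(model.threshold) == RiskClass.LOW
        assert model.classify(model.threshold + 1) == RiskClass.HIGH

    def test_null_counts_auc_near_half(self):
        aucs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            counts = rng.integers(0, 60, 100)
            labels = rng.integers(0, 2, 100)
            labels[:2] = [0, 1]
            aucs.append(youden_threshold(counts, labels).auc)
        assert abs(np.mean(aucs) - 0.5) < 0.1

    @given(st.integers(1, 50))
    @settings(max_examples=20)
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 40, 60)
        labels = rng.integers(0, 2, 60)
        labels[:2] = [0, 1]
        base = youden_threshold(counts, labels)
        transformed = youden_threshold(counts**3 + 2 * counts, labels)
        assert transformed.youden_j == pytest.approx(base.youden_j, abs=1e-12)
        assert transformed.auc == pytest.approx(base.auc, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            youden_threshold([1, 2, 3], [0, 0, 0])
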