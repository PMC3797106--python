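"""Breakpoint counts turned into a prognostic classifier.

The genome-wide breakpoint count is dichotomized by a strict cut-off: a
tumor with *more than* ``threshold`` breakpoints is called high-risk
genomic complexity, otherwise low-risk.  The cut-off is trained on a
labelled cohort by the Youden index (the threshold maximizing
sensitivity + specificity); the reference value from the original training
cohort is 34.  Sensitivity/specificity come with Wald 95% confidence
intervals, the AUC with a DeLong (default) or bootstrap interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

DEFAULT_THRESHOLD = 34
_Z95 = 1.959963984540054  # two-sided 95% normal quantile


class RiskClass:
    """Two-level genomic-complexity risk factor."""

    LOW = "low_risk"
    HIGH = "high_risk"


@dataclass
class ThresholdModel:
    """Trained breakpoint cut-off with its operating characteristics.

    The classification rule is strict: ``count > threshold`` is high-risk.
    ``table`` stores (good_low, good_high, poor_low, poor_high) at the
    trained threshold; sensitivity/specificity are recomputed from it.
    """

    threshold: int
    sensitivity: float
    specificity: float
    sensitivity_ci: tuple
    specificity_ci: tuple
    auc: float
    auc_ci: tuple
    youden_j: float
    table: tuple
    roc_points: np.ndarray = field(repr=False)  # (1 - specificity, sensitivity)

    def classify(self, count: int) -> str:
        return classify(count, self.threshold)

    def to_dict(self) -> dict:
        return {
            "threshold": int(self.threshold),
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "sensitivity_ci": list(self.sensitivity_ci),
            "specificity_ci": list(self.specificity_ci),
            "auc": self.auc,
            "auc_ci": list(self.auc_ci),
            "youden_j": self.youden_j,
            "table": list(self.table),
            "roc_points": np.asarray(self.roc_points).tolist(),
        }


def classify(count: int, threshold: int = DEFAULT_THRESHOLD) -> str:
    """Risk class of one tumor: high-risk iff count > threshold (strict)."""
    if count < 0:
        raise ValueError(f"breakpoint count must be >= 0, got {count}")
    return RiskClass.HIGH if count > threshold else RiskClass.LOW


def _wald_ci(p: float, n: int) -> tuple:
    half = _Z95 * np.sqrt(p * (1.0 - p) / n)
    return (max(0.0, p - half), min(1.0, p + half))


def contingency_stats(
    good_low: int, good_high: int, poor_low: int, poor_high: int
) -> dict:
    """Sensitivity and specificity (with Wald 95% CIs) of a 2x2 classification.

    Rows are the outcome groups (good = controls, poor = cases), columns the
    predicted class at the cut-off.  Specificity = good_low / (good total),
    sensitivity = poor_high / (poor total); intervals are the normal
    approximation p +/- 1.96 sqrt(p(1-p)/n) truncated to [0, 1].
    """
    cells = (good_low, good_high, poor_low, poor_high)
    if any(c < 0 or c != int(c) for c in cells):
        raise ValueError("contingency cells must be non-negative integers")
    n_good = good_low + good_high
    n_poor = poor_low + poor_high
    if n_good == 0 or n_poor == 0:
        raise ValueError("both outcome groups must be non-empty")
    specificity = good_low / n_good
    sensitivity = poor_high / n_poor
    return {
        "sensitivity": sensitivity,
        "specificity": specificity,
        "sensitivity_ci": _wald_ci(sensitivity, n_poor),
        "specificity_ci": _wald_ci(specificity, n_good),
        "table": cells,
    }


def _check_two_classes(counts, labels):
    counts = np.asarray(counts, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if counts.shape != labels.shape or counts.ndim != 1:
        raise ValueError("counts and labels must be 1-D and equally long")
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary (1 = poor prognosis)")
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    return counts, labels


def _delong_ci(pos, neg, auc):
    """DeLong variance of the empirical AUC via midrank placements."""
    m, n = len(pos), len(neg)
    all_vals = np.concatenate([pos, neg])
    rank_all = stats.rankdata(all_vals)
    v10 = (rank_all[:m] - stats.rankdata(pos)) / n  # P(neg < pos_i), ties half
    v01 = 1.0 - (rank_all[m:] - stats.rankdata(neg)) / m
    var = np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n
    half = _Z95 * np.sqrt(var)
    return (max(0.0, auc - half), min(1.0, auc + half))


def roc_auc(
    counts,
    labels,
    ci_method: str = "delong",
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple:
    """Empirical AUC (Mann-Whitney, ties counted 1/2) with a 95% CI.

    Positive class is poor prognosis (label 1); higher counts indicate
    positivity.  ``ci_method`` is ``"delong"`` (default) or ``"bootstrap"``
    (stratified, ``n_boot`` replicates, seeded).
    """
    counts, labels = _check_two_classes(counts, labels)
    pos = counts[labels == 1]
    neg = counts[labels == 0]
    ranks = stats.rankdata(counts)
    auc = (ranks[labels == 1].sum() - len(pos) * (len(pos) + 1) / 2) / (
        len(pos) * len(neg)
    )
    if ci_method == "delong":
        ci = _delong_ci(pos, neg, auc)
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        reps = np.empty(n_boot)
        for b in range(n_boot):
            p = rng.choice(pos, size=len(pos), replace=True)
            q = rng.choice(neg, size=len(neg), replace=True)
            reps[b] = (
                stats.rankdata(np.concatenate([p, q]))[: len(p)].sum()
                - len(p) * (len(p) + 1) / 2
            ) / (len(p) * len(q))
        ci = tuple(np.quantile(reps, [0.025, 0.975]))
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return float(auc), ci


def youden_threshold(counts, labels, ci_method: str = "delong", seed: int = 0) -> ThresholdModel:
    """Train the breakpoint cut-off maximizing sensitivity + specificity.

    Every achievable strict cut-off is scanned: the distinct observed
    counts plus a -1 sentinel (all-positive rule).  Ties in the Youden
    index J = sensitivity + specificity - 1 resolve to the smallest
    threshold.  The returned model stores the full ROC curve, the AUC with
    its 95% CI, and Wald intervals for the operating point.
    """
    counts, labels = _check_two_classes(counts, labels)
    pos = counts[labels == 1]
    neg = counts[labels == 0]
    cand = np.unique(np.concatenate([counts, [-1.0]]))
    sens = np.array([(pos > t).mean() for t in cand])
    spec = np.array([(neg <= t).mean() for t in cand])
    j = sens + spec - 1.0
    best = int(np.argmax(j))  # candidates ascending; first max = smallest threshold
    auc, auc_ci = roc_auc(counts, labels, ci_method=ci_method, seed=seed)
    threshold = cand[best]
    table = (
        int((neg <= threshold).sum()),
        int((neg > threshold).sum()),
        int((pos <= threshold).sum()),
        int((pos > threshold).sum()),
    )
    order = np.argsort(1.0 - spec, kind="stable")
    roc_points = np.column_stack([1.0 - spec, sens])[order]
    return ThresholdModel(
        threshold=int(threshold) if float(threshold).is_integer() else threshold,
        sensitivity=float(sens[best]),
        specificity=float(spec[best]),
        sensitivity_ci=_wald_ci(float(sens[best]), len(pos)),
        specificity_ci=_wald_ci(float(spec[best]), len(neg)),
        auc=auc,
        auc_ci=auc_ci,
        youden_j=float(j[best]),
        table=table,
        roc_points=roc_points,
    )
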