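"""Classification metrics (F1, rank-based AUC) and paired model comparisons.

AUC is computed as the Mann-Whitney pair statistic -- the probability that a
random positive scores above a random negative, ties counted half -- which is
exactly the area under the ROC curve and is well defined under ties.  Model
comparisons use the two tests of the study design: an (unpaired) Wilcoxon
rank-sum over the nine algorithm scores of the controlled vs uncontrolled
model groups, and a paired t-test over the per-iteration F1 differences of
the Monte Carlo cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ConfusionMatrix",
    "MetricValue",
    "TestResult",
    "confusion_from_predictions",
    "f1_score",
    "auc_score",
    "wilcoxon_rank_sum",
    "wilcoxon_signed_rank",
    "paired_t",
]


class MetricError(ValueError):
    """Raised on degenerate metric inputs."""


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts; ``positive_class_label`` documents class 1."""

    tp: int
    fp: int
    fn: int
    tn: int
    positive_class_label: str = "positive"

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise MetricError(f"{name} must be non-negative")

    @property
    def n_positives(self) -> int:
        return self.tp + self.fn

    @property
    def n_negatives(self) -> int:
        return self.fp + self.tn

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricValue:
    name: str
    value: float

    def __post_init__(self) -> None:
        if self.name not in ("F1", "AUC"):
            raise MetricError(f"unknown metric {self.name!r}")
        if not (0.0 <= self.value <= 1.0):
            raise MetricError(f"{self.name} = {self.value} outside [0, 1]")


@dataclass(frozen=True)
class TestResult:
    """Statistic + two-sided p, with a 95% CI where the test defines one."""

    statistic: float
    p_value: float
    mean_difference: float = float("nan")
    ci95_low: float = float("nan")
    ci95_high: float = float("nan")

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise MetricError(f"p-value {self.p_value} outside [0, 1]")


def confusion_from_predictions(
    y_true, y_pred, positive_class_label: str = "positive"
) -> ConfusionMatrix:
    yt = np.asarray(y_true, dtype=bool)
    yp = np.asarray(y_pred, dtype=bool)
    if yt.shape != yp.shape:
        raise MetricError("y_true and y_pred must have the same length")
    return ConfusionMatrix(
        tp=int(np.sum(yt & yp)),
        fp=int(np.sum(~yt & yp)),
        fn=int(np.sum(yt & ~yp)),
        tn=int(np.sum(~yt & ~yp)),
        positive_class_label=positive_class_label,
    )


def f1_score(cm: ConfusionMatrix) -> MetricValue:
    """F1 = 2 TP / (2 TP + FP + FN); 0 when TP = 0 but errors exist."""
    denom = 2 * cm.tp + cm.fp + cm.fn
    if denom == 0:
        raise MetricError("F1 undefined: no positives predicted or present")
    return MetricValue("F1", 2 * cm.tp / denom)


def auc_score(scores_pos, scores_neg) -> MetricValue:
    """Rank-statistic AUC: (#{s+ > s-} + 0.5 #{s+ = s-}) / (n+ n-)."""
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise MetricError("AUC requires at least one positive and one negative score")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    rank_sum_pos = ranks[: pos.size].sum()
    u = rank_sum_pos - pos.size * (pos.size + 1) / 2.0
    return MetricValue("AUC", float(u / (pos.size * neg.size)))


def wilcoxon_rank_sum(x, y, exact_max_n: int = 30) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact distribution when there are no ties and the combined sample size is
    at most ``exact_max_n``; tie-corrected normal approximation with
    continuity correction otherwise.  Identical samples give p = 1 by
    convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise MetricError("rank-sum test requires >= 2 values per group")
    if np.ptp(np.concatenate([x, y])) == 0:
        return TestResult(statistic=x.size * y.size / 2.0, p_value=1.0,
                          mean_difference=0.0)
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (not has_ties and x.size + y.size <= exact_max_n) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(1.0, res.pvalue)),
        mean_difference=float(np.mean(x) - np.mean(y)),
    )


def wilcoxon_signed_rank(x, y) -> TestResult:
    """Paired signed-rank alternative, for sensitivity analysis (off by default)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    d = x - y
    if np.all(d == 0):
        return TestResult(statistic=0.0, p_value=1.0, mean_difference=0.0)
    res = stats.wilcoxon(x, y, alternative="two-sided")
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        mean_difference=float(np.mean(d)),
    )


def paired_t(differences) -> TestResult:
    """Paired t-test on a vector of differences, with the 95% CI of the mean.

    t = mean / (sd / sqrt(n)) on n-1 degrees of freedom, two-sided.
    """
    d = np.asarray(differences, dtype=float)
    if d.size < 2:
        raise MetricError("paired t-test requires >= 2 differences")
    sd = d.std(ddof=1)
    if sd == 0:
        raise MetricError("paired t-test degenerate: zero variance of differences")
    n = d.size
    mean = d.mean()
    se = sd / np.sqrt(n)
    t = mean / se
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    half = stats.t.ppf(0.975, df=n - 1) * se
    return TestResult(
        statistic=float(t),
        p_value=float(min(1.0, p)),
        mean_difference=float(mean),
        ci95_low=float(mean - half),
        ci95_high=float(mean + half),
    )
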