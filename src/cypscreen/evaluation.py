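"""Confusion-matrix metrics and paired classifier comparison.

The positive class throughout is "inhibitor".  Accuracy, sensitivity,
specificity and balanced accuracy are reported as percentages; the Matthews
correlation coefficient (MCC) is a fraction in [-1, 1] and additionally
reported x100 for table parity with the percentage columns.

Two classifiers evaluated on the same test set are compared with the exact
McNemar test on discordant correctness pairs: under the null of equal error
rates the number of rows only classifier A gets right is Binomial(b+c, 1/2).
A two-proportion z-test is available as a sensitivity check for unpaired
comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import CypscreenError


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts with "inhibitor" as the positive class."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


@dataclass(frozen=True)
class MetricsReport:
    """Percent-scale classification metrics plus the MCC fraction."""

    accuracy: float
    sensitivity: float
    specificity: float
    balanced_accuracy: float
    mcc: float  # fraction in [-1, 1]

    @property
    def mcc_pct(self) -> float:
        return 100.0 * self.mcc


def confusion(predicted, truth, positive: str | int = "inhibitor") -> ConfusionMatrix:
    """Count tp/fn/tn/fp for binary label vectors of equal length."""
    predicted = list(predicted)
    truth = list(truth)
    if len(predicted) != len(truth):
        raise CypscreenError(
            f"prediction/truth length mismatch: {len(predicted)} vs {len(truth)}"
        )
    classes = set(predicted) | set(truth)
    if len(classes) > 2:
        raise CypscreenError(f"labels must be binary, got {sorted(map(str, classes))}")
    tp = fn = tn = fp = 0
    for p, t in zip(predicted, truth):
        if t == positive:
            if p == positive:
                tp += 1
            else:
                fn += 1
        else:
            if p == positive:
                fp += 1
            else:
                tn += 1
    return ConfusionMatrix(tp=tp, fn=fn, tn=tn, fp=fp)


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Standard binary metrics; MCC returns 0 when any marginal is zero."""
    pos = cm.tp + cm.fn
    neg = cm.tn + cm.fp
    if pos == 0 or neg == 0:
        raise CypscreenError("metrics require both classes present in the truth")
    sens = cm.tp / pos
    spec = cm.tn / neg
    acc = (cm.tp + cm.tn) / cm.total
    denom = (cm.tp + cm.fp) * (cm.tp + cm.fn) * (cm.tn + cm.fp) * (cm.tn + cm.fn)
    if denom == 0:
        mcc = 0.0
    else:
        mcc = (cm.tp * cm.tn - cm.fp * cm.fn) / np.sqrt(denom)
    return MetricsReport(
        accuracy=100.0 * acc,
        sensitivity=100.0 * sens,
        specificity=100.0 * spec,
        balanced_accuracy=100.0 * (sens + spec) / 2.0,
        mcc=float(mcc),
    )


def compare_classifiers(preds_a, preds_b, truth, method: str = "mcnemar") -> dict:
    """Paired significance test of two classifiers on one test set.

    ``mcnemar`` (default): exact binomial test on the discordant pairs
    (b = rows only A gets right, c = rows only B gets right);
    two-sided p = min(1, 2 * P(X <= min(b, c))) with X ~ Binomial(b+c, 1/2).
    ``ztest``: unpaired two-proportion z-test on the accuracies.
    """
    preds_a, preds_b, truth = list(preds_a), list(preds_b), list(truth)
    if not len(preds_a) == len(preds_b) == len(truth):
        raise CypscreenError("all three label vectors must have the same length")
    correct_a = np.array([p == t for p, t in zip(preds_a, truth)])
    correct_b = np.array([p == t for p, t in zip(preds_b, truth)])
    b = int(np.sum(correct_a & ~correct_b))
    c = int(np.sum(~correct_a & correct_b))
    if method == "mcnemar":
        n = b + c
        if n == 0:
            p_value = 1.0
        else:
            k = min(b, c)
            p_value = min(1.0, 2.0 * float(stats.binom.cdf(k, n, 0.5)))
        return {"method": "mcnemar_exact", "b": b, "c": c, "statistic": float(min(b, c)), "p_value": p_value}
    if method == "ztest":
        n = len(truth)
        acc_a, acc_b = correct_a.mean(), correct_b.mean()
        pooled = (correct_a.sum() + correct_b.sum()) / (2 * n)
        se = np.sqrt(pooled * (1 - pooled) * 2 / n)
        z = 0.0 if se == 0 else (acc_a - acc_b) / se
        p_value = 2 * float(stats.norm.sf(abs(z)))
        return {"method": "two_proportion_z", "b": b, "c": c, "statistic": float(z), "p_value": p_value}
    raise ValueError(f"unknown method {method!r}")


def format_report(rows: dict[str, MetricsReport]) -> str:
    """Delimited table: rows = model/descriptor-set names, percentage
    columns to 2 decimals, MCC reported x100."""
    lines = ["model\taccuracy_pct\tsensitivity_pct\tspecificity_pct\tmcc_pct"]
    for name, r in rows.items():
        lines.append(
            f"{name}\t{r.accuracy:.2f}\t{r.sensitivity:.2f}\t{r.specificity:.2f}\t{r.mcc_pct:.2f}"
        )
    return "\n".join(lines) + "\n"
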