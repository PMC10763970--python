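"""Confusion accounting, macro metrics, cross-validation, paired t-tests.

Per-class precision, recall and F1 are computed by one-vs-rest reduction of
the multi-class confusion matrix:

    precision_c = TP_c / (TP_c + FP_c)
    recall_c    = TP_c / (TP_c + FN_c)
    F1_c        = 2 * precision_c * recall_c / (precision_c + recall_c)

with the 0/0 case defined as 0.  Macro averages are unweighted means over
classes, so minority classes count as much as the majority class — the
point of macro averaging on imbalanced cohorts.  Accuracy is the trace of
the confusion matrix over the total.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Sequence

import numpy as np
from scipy import stats
from sklearn.model_selection import KFold

from .data_io import EncodedMatrix

__all__ = [
    "ConfusionMatrix",
    "ClassMetrics",
    "MetricReport",
    "CVResult",
    "TTestResult",
    "confusion_matrix",
    "per_class_metrics",
    "macro_average",
    "accuracy",
    "metric_report",
    "kfold_cv",
    "paired_ttest",
    "model_score_vector",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding, so printed tables are well-defined."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ConfusionMatrix:
    """C x C counts; rows are true classes, columns predicted classes."""

    counts: np.ndarray
    class_map: dict[str, int]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        C = len(self.class_map)
        if self.counts.shape != (C, C):
            raise ValueError("counts must be C x C for the class map")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, idx: int) -> tuple[int, int, int, int]:
        """(TP, FP, FN, TN) treating class ``idx`` as positive."""
        tp = int(self.counts[idx, idx])
        fp = int(self.counts[:, idx].sum()) - tp
        fn = int(self.counts[idx, :].sum()) - tp
        tn = self.total - tp - fp - fn
        return tp, fp, fn, tn


def confusion_matrix(
    y_true: Sequence[int], y_pred: Sequence[int], class_map: dict[str, int]
) -> ConfusionMatrix:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    C = len(class_map)
    if y_true.size and (
        y_true.min() < 0 or y_true.max() >= C or y_pred.min() < 0 or y_pred.max() >= C
    ):
        raise ValueError("labels outside the class map's index range")
    counts = np.zeros((C, C), dtype=int)
    np.add.at(counts, (y_true, y_pred), 1)
    return ConfusionMatrix(counts, dict(class_map))


@dataclass
class ClassMetrics:
    class_code: str
    precision: float
    recall: float
    f1: float
    support: int


def _safe_div(num: float, den: float) -> float:
    return num / den if den else 0.0


def per_class_metrics(cm: ConfusionMatrix) -> list[ClassMetrics]:
    """One-vs-rest precision/recall/F1 per class; 0/0 cases are 0."""
    out = []
    for code, idx in cm.class_map.items():
        tp, fp, fn, _ = cm.one_vs_rest(idx)
        p = _safe_div(tp, tp + fp)
        r = _safe_div(tp, tp + fn)
        f1 = _safe_div(2 * p * r, p + r)
        out.append(ClassMetrics(code, p, r, f1, support=tp + fn))
    return out


def macro_average(
    per_class: Sequence[ClassMetrics],
) -> tuple[float, float, float]:
    """Unweighted mean of per-class precision, recall and F1."""
    if not per_class:
        raise ValueError("cannot macro-average an empty class list")
    p = float(np.mean([c.precision for c in per_class]))
    r = float(np.mean([c.recall for c in per_class]))
    f1 = float(np.mean([c.f1 for c in per_class]))
    return p, r, f1


def accuracy(cm: ConfusionMatrix) -> float:
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts)) / cm.total


@dataclass
class MetricReport:
    accuracy: float
    per_class: list[ClassMetrics]
    macro_precision: float
    macro_recall: float
    macro_f1: float
    confusion: ConfusionMatrix | None = None

    def to_dict(self) -> dict:
        d = {
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "per_class": [
                {
                    "class": c.class_code,
                    "precision": c.precision,
                    "recall": c.recall,
                    "f1": c.f1,
                    "support": c.support,
                }
                for c in self.per_class
            ],
        }
        if self.confusion is not None:
            d["confusion"] = self.confusion.counts.tolist()
            d["class_map"] = dict(self.confusion.class_map)
        return d

    def to_markdown(self, ndigits: int = 2) -> str:
        rnd = lambda v: f"{round_half_up(v, ndigits):.{ndigits}f}"
        lines = [
            "| Class | Precision | Recall | F1 | Support |",
            "|---|---|---|---|---|",
        ]
        for c in self.per_class:
            lines.append(
                f"| {c.class_code} | {rnd(c.precision)} | {rnd(c.recall)} "
                f"| {rnd(c.f1)} | {c.support} |"
            )
        lines.append(
            f"| Macro average | {rnd(self.macro_precision)} "
            f"| {rnd(self.macro_recall)} | {rnd(self.macro_f1)} | |"
        )
        lines.append("")
        lines.append(f"Accuracy: {round_half_up(self.accuracy, 3)}")
        return "\n".join(lines)


def metric_report(
    y_true: Sequence[int], y_pred: Sequence[int], class_map: dict[str, int]
) -> MetricReport:
    """Full evaluation of one prediction vector: accuracy, per-class and
    macro precision/recall/F1, with the confusion matrix attached."""
    cm = confusion_matrix(y_true, y_pred, class_map)
    per_class = per_class_metrics(cm)
    mp, mr, mf1 = macro_average(per_class)
    return MetricReport(accuracy(cm), per_class, mp, mr, mf1, confusion=cm)


@dataclass
class CVResult:
    fold_accuracies: list[float]
    mean_accuracy: float
    sd: float
    elapsed_seconds: float
    k: int
    seed: int


def kfold_cv(
    model_factory: Callable[[], object],
    data: EncodedMatrix,
    k: int = 10,
    seed: int = 0,
) -> CVResult:
    """Seeded shuffled k-fold cross-validation reporting accuracy.

    Each fold is scored by a model fit on the fold's complement; mean and
    sample (n-1) standard deviation summarize the k accuracies.  Wall time
    is recorded for reporting but is hardware-dependent and never asserted.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > data.n:
        raise ValueError(f"k={k} exceeds n={data.n}")
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    start = time.perf_counter()
    scores = []
    for fit_idx, held_idx in kf.split(data.X):
        model = model_factory()
        model.fit(data.X[fit_idx], data.y[fit_idx])
        pred = np.asarray(model.predict(data.X[held_idx]), dtype=int)
        scores.append(float(np.mean(pred == data.y[held_idx])))
    elapsed = time.perf_counter() - start
    sd = float(np.std(scores, ddof=1)) if k > 1 else 0.0
    return CVResult(scores, float(np.mean(scores)), sd, elapsed, k, seed)


@dataclass
class TTestResult:
    t_statistic: float
    df: int
    p_value: float
    alpha: float
    reject_null: bool


def paired_ttest(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    alpha: float = 0.05,
) -> TTestResult:
    """Two-sided paired t-test on score differences.

    t = mean(d) / (sd(d) / sqrt(n)) with df = n - 1.  Identical vectors
    give t = 0 (no rejection); a non-zero constant difference has zero
    variance and is reported as an infinite t with p = 0.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("score vectors must have equal length")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 paired observations")
    d = a - b
    df = n - 1
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        if mean == 0.0:
            t, p = 0.0, 1.0
        else:
            t, p = float(np.sign(mean)) * float("inf"), 0.0
    else:
        t = mean / (sd / np.sqrt(n))
        p = 2.0 * float(stats.t.sf(abs(t), df))
    return TTestResult(t, df, p, alpha, reject_null=p < alpha)


def model_score_vector(reports: Sequence[MetricReport]) -> np.ndarray:
    """Flatten a model's evaluation into one score vector for comparison.

    Each report contributes (accuracy, macro precision, macro recall,
    macro F1); with the two data settings (original and down-sampled) this
    yields eight paired observations per model, hence df = 7 in the paired
    t-test between two models.
    """
    out = []
    for r in reports:
        out.extend([r.accuracy, r.macro_precision, r.macro_recall, r.macro_f1])
    return np.asarray(out, dtype=float)
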