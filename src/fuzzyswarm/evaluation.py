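"""Confusion matrix, classification metrics and cross-validation.

The confusion matrix is kept in the clinical orientation (rows = classifier
result, columns = angiography result).  An unclassified instance (no winner
rule) is always an error against its true class: a false negative when the
instance is truly positive, a false positive otherwise.  Besides the usual
accuracy / sensitivity / specificity / precision / F for the designated
positive class, per-class precision, recall and F are reported for both
classes, since with asymmetric class sizes the two families differ
materially.  Undefined ratios (zero denominators) are reported as NaN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Hashable, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .boosting import WeightedDataset
from .ensemble import RuleSet, TrainConfig, train
from .fuzzy_core import Instance


@dataclass
class ConfusionMatrix:
    """Binary 2x2 tally with an explicit positive class."""

    tp: int
    tn: int
    fp: int
    fn: int
    positive_class: Hashable = "patient"
    negative_class: Hashable = "healthy"

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def swapped(self) -> "ConfusionMatrix":
        """The same tally with the opposite positive-class convention."""
        return ConfusionMatrix(
            tp=self.tn, tn=self.tp, fp=self.fn, fn=self.fp,
            positive_class=self.negative_class, negative_class=self.positive_class,
        )

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if (self.positive_class, self.negative_class) != (other.positive_class, other.negative_class):
            raise ValueError("cannot pool matrices with different class conventions")
        return ConfusionMatrix(
            self.tp + other.tp, self.tn + other.tn, self.fp + other.fp, self.fn + other.fn,
            self.positive_class, self.negative_class,
        )

    def pretty(self) -> str:
        """Rows = classifier result, columns = true (angiography) result."""
        p, n = str(self.positive_class), str(self.negative_class)
        w = max(len(p), len(n), 6)
        lines = [
            f"{'':>{w}}  {p:>{w}}  {n:>{w}}   (actual)",
            f"{p:>{w}}  {self.tp:>{w}}  {self.fp:>{w}}",
            f"{n:>{w}}  {self.fn:>{w}}  {self.tn:>{w}}",
        ]
        return "\n".join(lines)


def confusion(
    true_labels: Sequence[Hashable],
    predicted: Sequence[Hashable],
    positive_class: Hashable = "patient",
    negative_class: Hashable | None = None,
) -> ConfusionMatrix:
    """Tally predictions against truth; ``None`` predictions (unclassified)
    count against the true class."""
    if len(true_labels) != len(predicted):
        raise ValueError("label/prediction length mismatch")
    labels = set(true_labels)
    if negative_class is None:
        rest = labels - {positive_class}
        if len(rest) > 1:
            raise ValueError("more than two classes; specify negative_class")
        negative_class = rest.pop() if rest else "negative"
    known = {positive_class, negative_class}
    tp = tn = fp = fn = 0
    for t, p in zip(true_labels, predicted):
        if t not in known or (p is not None and p not in known):
            raise ValueError(f"unknown label {t!r}/{p!r}")
        if t == positive_class:
            if p == positive_class:
                tp += 1
            else:  # wrong prediction or unclassified
                fn += 1
        else:
            if p == negative_class:
                tn += 1
            else:
                fp += 1
    return ConfusionMatrix(tp, tn, fp, fn, positive_class, negative_class)


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


@dataclass
class ClassMetrics:
    precision: float
    recall: float
    f_measure: float


@dataclass
class MetricReport:
    """The five headline metrics (fractions in [0, 1]; multiply by 100 for
    percent) plus per-class precision/recall/F for both classes."""

    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f_measure: float
    per_class: dict[Hashable, ClassMetrics] = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "f_measure": self.f_measure,
        }
        for h, cm in self.per_class.items():
            d[f"{h}_precision"] = cm.precision
            d[f"{h}_recall"] = cm.recall
            d[f"{h}_f_measure"] = cm.f_measure
        return d


def metrics(cm: ConfusionMatrix) -> MetricReport:
    """accuracy = (TP+TN)/total, sensitivity = recall = TP/(TP+FN),
    specificity = TN/(TN+FP), precision = TP/(TP+FP), F = harmonic mean of
    precision and recall.  Zero denominators yield NaN."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    prec = _ratio(cm.tp, cm.tp + cm.fp)
    rec = _ratio(cm.tp, cm.tp + cm.fn)
    f = _ratio(2 * prec * rec, prec + rec) if not (math.isnan(prec) or math.isnan(rec)) else math.nan
    sw = cm.swapped()
    nprec = _ratio(sw.tp, sw.tp + sw.fp)
    nrec = _ratio(sw.tp, sw.tp + sw.fn)
    nf = _ratio(2 * nprec * nrec, nprec + nrec) if not (math.isnan(nprec) or math.isnan(nrec)) else math.nan
    return MetricReport(
        accuracy=(cm.tp + cm.tn) / cm.total,
        sensitivity=rec,
        specificity=_ratio(cm.tn, cm.tn + cm.fp),
        precision=prec,
        f_measure=f,
        per_class={
            cm.positive_class: ClassMetrics(prec, rec, f),
            cm.negative_class: ClassMetrics(nprec, nrec, nf),
        },
    )


@dataclass
class FoldResult:
    fold: int
    confusion: ConfusionMatrix
    report: MetricReport
    n_rules: int
    mean_rule_length: float


@dataclass
class CVResult:
    folds: list[FoldResult]
    pooled: ConfusionMatrix
    pooled_report: MetricReport

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean([f.report.accuracy for f in self.folds]))

    @property
    def mean_rules(self) -> float:
        return float(np.mean([f.n_rules for f in self.folds]))

    @property
    def mean_rule_length(self) -> float:
        return float(np.mean([f.mean_rule_length for f in self.folds]))

    def tsv(self) -> str:
        cols = ["fold", "accuracy", "sensitivity", "specificity", "precision", "f_measure", "n_rules", "mean_rule_length"]
        lines = ["\t".join(cols)]
        for f in self.folds:
            r = f.report
            lines.append(
                "\t".join(
                    [str(f.fold)]
                    + [f"{v:.6g}" for v in (r.accuracy, r.sensitivity, r.specificity, r.precision, r.f_measure)]
                    + [str(f.n_rules), f"{f.mean_rule_length:.6g}"]
                )
            )
        r = self.pooled_report
        lines.append(
            "\t".join(
                ["pooled"]
                + [f"{v:.6g}" for v in (r.accuracy, r.sensitivity, r.specificity, r.precision, r.f_measure)]
                + [f"{self.mean_rules:.6g}", f"{self.mean_rule_length:.6g}"]
            )
        )
        return "\n".join(lines) + "\n"


def cross_validate(
    instances: Sequence[Instance],
    cfg: TrainConfig,
    k: int = 10,
    rng: np.random.Generator | None = None,
    positive_class: Hashable = "patient",
) -> CVResult:
    """Stratified k-fold cross-validation of the full training loop.

    Folds are stratified by class (each instance validates exactly once);
    every class must have at least ``k`` members.  Metrics are averaged over
    folds and confusion counts pooled.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng() if rng is None else rng
    X = np.stack([i.values for i in instances])
    y = np.array([i.label for i in instances], dtype=object)
    counts = {h: int((y == h).sum()) for h in set(y.tolist())}
    if min(counts.values()) < k:
        raise ValueError(f"stratification impossible: smallest class has {min(counts.values())} < k={k} members")
    classes = sorted(counts, key=str)
    if positive_class not in classes or len(classes) != 2:
        raise ValueError(f"binary evaluation needs positive_class among exactly two classes, got {classes}")
    negative = next(h for h in classes if h != positive_class)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(rng.integers(2**31 - 1)))
    folds: list[FoldResult] = []
    pooled: ConfusionMatrix | None = None
    y_str = y.astype(str)
    for fold, (tr, te) in enumerate(skf.split(X, y_str), start=1):
        data = WeightedDataset(X=X[tr], labels=y[tr])
        rs = train(data, cfg, rng)
        pred = rs.predict(X[te])
        cm = confusion(list(y[te]), pred, positive_class=positive_class, negative_class=negative)
        count, mean_len = rs.stats()
        folds.append(FoldResult(fold, cm, metrics(cm), count, mean_len))
        pooled = cm if pooled is None else pooled + cm
    return CVResult(folds=folds, pooled=pooled, pooled_report=metrics(pooled))
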