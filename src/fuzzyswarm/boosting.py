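"""Boosting-style instance reweighting between rule-extraction runs.

Every training instance carries a weight, initialised to 1.  After a rule is
accepted into the rule set, the weights of the instances it classifies
correctly are multiplicatively decayed — the more compatible the instance is
with the rule antecedent, and the smaller the rule's weighted error, the
stronger the decay.  Misclassified and uncovered instances keep their weight
bit-for-bit, so subsequent swarm runs concentrate on them.  Unlike classical
AdaBoost there is no renormalisation and no hypothesis weighting by error:
rules are weighted by their certainty factor at inference time, and training
stops when the total remaining weight drops below a threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Sequence

import numpy as np

from .fuzzy_core import (
    FuzzyRule,
    Instance,
    compatibility_from_codes,
    membership_table,
)


@dataclass
class WeightedDataset:
    """Scaled instances with class labels and boosting weights.

    ``X`` is ``(m, n)`` with values in [0, 1] or NaN for missing; weights
    start at 1 and only ever shrink (multiplicative factors are <= 1).
    """

    X: np.ndarray
    labels: np.ndarray
    weights: np.ndarray = None  # type: ignore[assignment]
    _table: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (instances x attributes)")
        self.labels = np.asarray(self.labels, dtype=object)
        if self.weights is None:
            self.weights = np.ones(self.X.shape[0])
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.labels) != self.X.shape[0] or len(self.weights) != self.X.shape[0]:
            raise ValueError("labels/weights length mismatch")
        if (self.weights < 0).any():
            raise ValueError("weights must be nonnegative")

    @classmethod
    def from_instances(cls, instances: Iterable[Instance]) -> "WeightedDataset":
        inst = list(instances)
        X = np.stack([i.values for i in inst])
        labels = np.array([i.label for i in inst], dtype=object)
        weights = np.array([i.weight for i in inst], dtype=float)
        return cls(X=X, labels=labels, weights=weights)

    def to_instances(self) -> list[Instance]:
        return [Instance(x, l, w) for x, l, w in zip(self.X, self.labels, self.weights)]

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def n_attributes(self) -> int:
        return self.X.shape[1]

    @property
    def total_weight(self) -> float:
        return float(self.weights.sum())

    @property
    def classes(self) -> list[Hashable]:
        return sorted(set(self.labels.tolist()), key=str)

    def membership_table(self) -> np.ndarray:
        """Cached per-symbol membership table for the instance matrix."""
        if self._table is None:
            self._table = membership_table(self.X)
        return self._table

    def compatibility(self, rule: FuzzyRule) -> np.ndarray:
        """Compatibility of every instance with ``rule`` (vectorised)."""
        if rule.n_attributes != self.n_attributes:
            raise ValueError("rule/attribute-count mismatch")
        return compatibility_from_codes(rule.codes(), self.membership_table())

    def reset_weights(self) -> None:
        self.weights = np.ones(len(self))


def rule_error(rule: FuzzyRule, data: WeightedDataset) -> float:
    """Weighted, compatibility-graded error of a rule.

    ER = sum(w_k mu(x_k) over instances of the wrong class) / sum(w_k mu(x_k)).
    A rule covering nothing (zero denominator) has ER = 0 by convention.
    """
    mu = data.compatibility(rule)
    den = float((data.weights * mu).sum())
    if den <= 0.0:
        return 0.0
    wrong = data.labels != rule.consequent
    num = float((data.weights * mu * wrong).sum())
    return num / den


def alpha_factor(mu: float, er: float, w: float) -> float:
    """Multiplicative weight-decay factor for one correctly classified instance.

    alpha = (1 / (1 + exp(mu / (ER + w))))^mu; mu = 0 gives exactly 1 (the
    weight of an uncovered instance is untouched).  Strictly decreasing in mu
    at fixed ER and w.
    """
    if mu == 0.0:
        return 1.0
    if er + w <= 0.0:
        raise ZeroDivisionError("alpha factor undefined: ER + w == 0 with mu > 0")
    return (1.0 / (1.0 + math.exp(mu / (er + w)))) ** mu


def update_weights(rule: FuzzyRule, data: WeightedDataset) -> WeightedDataset:
    """Decay the weights of instances the rule classifies correctly.

    Instances whose label equals the rule consequent get ``w <- w * alpha``
    (alpha from their own compatibility and current weight, and the rule's
    error on the current weights); all other weights are returned unchanged
    bit-for-bit.  Mutates ``data`` in place and returns it.
    """
    er = rule_error(rule, data)
    mu = data.compatibility(rule)
    w = data.weights
    # zero-weight instances are left alone (their decayed value is 0 anyway,
    # and skipping them keeps ER + w strictly positive below)
    touch = (data.labels == rule.consequent) & (mu > 0.0) & (w > 0.0)
    if touch.any():
        mt, wt = mu[touch], w[touch]
        with np.errstate(over="ignore"):  # exp overflow -> alpha underflows to 0
            alpha = (1.0 / (1.0 + np.exp(mt / (er + wt)))) ** mt
        w[touch] = wt * alpha
    return data
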