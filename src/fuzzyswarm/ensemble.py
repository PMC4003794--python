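"""Outer training loop: repeated swarm runs, rule accumulation, boosting.

Training alternates swarm searches and weight updates: each run extracts up
to B rules fitted to the current instance weights; every accepted rule then
decays the weights of the instances it classifies correctly, so the next run
concentrates on what is still uncovered or misclassified.  The loop stops
when the total remaining weight falls below the threshold K (default 12),
with a run cap and a no-progress stop as safety guards.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Hashable, Sequence

import numpy as np

from . import fuzzy_core
from .boosting import WeightedDataset, update_weights
from .fuzzy_core import FuzzyRule, decode
from .ram_pso import SwarmConfig, pso_run

FORMAT_VERSION = 1


@dataclass
class TrainConfig:
    """Ensemble-loop parameters: total-weight stop K, run cap, swarm config."""

    weight_stop: float = 12.0  # K: stop once sum of instance weights <= K
    max_runs: int = 50
    swarm: SwarmConfig = field(default_factory=SwarmConfig)

    def __post_init__(self) -> None:
        if self.weight_stop <= 0:
            raise ValueError("weight_stop (K) must be positive")
        if self.max_runs < 1:
            raise ValueError("max_runs must be >= 1")

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        swarm = SwarmConfig.from_dict(d.get("swarm", {}))
        kw = {k: d[k] for k in ("weight_stop", "max_runs") if k in d}
        return cls(swarm=swarm, **kw)

    def to_dict(self) -> dict:
        return {
            "weight_stop": self.weight_stop,
            "max_runs": self.max_runs,
            "swarm": {
                "swarm_size": self.swarm.swarm_size,
                "n_rules": self.swarm.n_rules,
                "g_threshold": self.swarm.g_threshold,
                "stall_limit": self.swarm.stall_limit,
                "max_iters": self.swarm.max_iters,
                "dc_prob": self.swarm.dc_prob,
            },
        }


class RuleSet:
    """An ordered, duplicate-free collection of positive-CF fuzzy rules with
    winner-rule inference and per-rule provenance (the run that produced it).
    """

    def __init__(self, n_attributes: int, attribute_names: Sequence[str] | None = None):
        self.n_attributes = n_attributes
        self.attribute_names = list(attribute_names) if attribute_names else [f"x{i+1}" for i in range(n_attributes)]
        self.rules: list[FuzzyRule] = []
        self.provenance: list[int] = []
        self.history: list[dict] = []
        self._keys: set[tuple[str, Hashable]] = set()

    def __len__(self) -> int:
        return len(self.rules)

    def __iter__(self):
        return iter(self.rules)

    def __contains__(self, rule: FuzzyRule) -> bool:
        return (rule.encode(), rule.consequent) in self._keys

    def add(self, rule: FuzzyRule, run: int = 0) -> bool:
        """Append a rule unless an equal antecedent+class rule is present;
        rules without positive CF are rejected."""
        if rule.n_attributes != self.n_attributes:
            raise ValueError("rule/attribute-count mismatch")
        if rule.cf <= 0.0:
            raise ValueError("only rules with positive certainty factor are stored")
        if rule in self:
            return False
        self.rules.append(rule)
        self.provenance.append(run)
        self._keys.add((rule.encode(), rule.consequent))
        return True

    def predict(self, X: np.ndarray) -> list:
        """Winner-rule label per row of ``X`` (``None`` = unclassified)."""
        return fuzzy_core.classify_batch(self.rules, X)

    def stats(self) -> tuple[int, float]:
        """Rule count and mean number of active antecedents (0 when empty)."""
        if not self.rules:
            return 0, 0.0
        return len(self.rules), float(np.mean([r.length for r in self.rules]))

    # -- serialization ------------------------------------------------------

    def to_tsv(self) -> str:
        """One rule per line: ``<antecedents>\\t<class>\\t<cf>``."""
        return "".join(f"{r.encode()}\t{r.consequent}\t{r.cf:.17g}\n" for r in self.rules)

    @classmethod
    def from_tsv(cls, text: str, n_attributes: int | None = None) -> "RuleSet":
        rules = []
        for line in text.splitlines():
            if not line.strip():
                continue
            ant, cls_label, cf = line.split("\t")
            rules.append(decode(ant, cls_label, float(cf)))
        if n_attributes is None:
            if not rules:
                raise ValueError("cannot infer attribute count from an empty file")
            n_attributes = rules[0].n_attributes
        rs = cls(n_attributes)
        for r in rules:
            rs.add(r)
        return rs

    def to_json(self) -> str:
        doc = {
            "version": FORMAT_VERSION,
            "n_attributes": self.n_attributes,
            "attribute_names": self.attribute_names,
            "rules": [
                {"antecedents": r.encode(), "class": r.consequent, "cf": r.cf, "run": run}
                for r, run in zip(self.rules, self.provenance)
            ],
        }
        return json.dumps(doc, indent=2, default=str)

    @classmethod
    def from_json(cls, text: str) -> "RuleSet":
        doc = json.loads(text)
        rs = cls(doc["n_attributes"], doc.get("attribute_names"))
        for rec in doc["rules"]:
            rs.add(decode(rec["antecedents"], rec["class"], rec["cf"]), rec.get("run", 0))
        return rs


def train(data: WeightedDataset, cfg: TrainConfig, rng: np.random.Generator) -> RuleSet:
    """Run the full boosted-swarm training loop on ``data``.

    Instance weights must start at 1 (they are reset here).  Returns the
    accumulated rule set; ``RuleSet.history`` carries one record per run
    (rules added, remaining total weight, cumulative training accuracy) for
    learning-curve inspection.
    """
    if len(data.classes) < 2:
        raise ValueError("training requires at least two classes")
    data.reset_weights()
    rs = RuleSet(data.n_attributes)
    empty_streak = 0
    for run in range(1, cfg.max_runs + 1):
        if data.total_weight <= cfg.weight_stop:
            break
        rules = pso_run(data, cfg.swarm, rng)
        added = 0
        for r in rules:
            if rs.add(r, run):
                added += 1
                # re-derive the rule's error on the *current* weights, then decay
                update_weights(r, data)
        pred = rs.predict(data.X)
        acc = float(np.mean([p == t for p, t in zip(pred, data.labels)]))
        rs.history.append(
            {
                "run": run,
                "rules_added": added,
                "rules_total": len(rs),
                "total_weight": data.total_weight,
                "train_accuracy": acc,
            }
        )
        if added == 0:
            empty_streak += 1
            if empty_streak >= 2:
                break
        else:
            empty_streak = 0
    return rs


def predict(rs: RuleSet, instances) -> list:
    """Winner-rule labels for instances (array, list of Instance, or
    WeightedDataset); ``None`` marks unclassified instances."""
    if isinstance(instances, WeightedDataset):
        X = instances.X
    elif isinstance(instances, (list, tuple)) and instances and isinstance(instances[0], fuzzy_core.Instance):
        X = np.stack([i.values for i in instances])
    else:
        X = np.atleast_2d(np.asarray(instances, dtype=float))
    if X.shape[1] != rs.n_attributes:
        raise ValueError("attribute-count mismatch between rules and instances")
    return rs.predict(X)


def ruleset_stats(rs: RuleSet) -> tuple[int, float]:
    """(rule count, mean active-antecedent length); (0, 0.0) when empty."""
    return rs.stats()


def history_tsv(rs: RuleSet) -> str:
    """The training log as tab-separated text (one line per swarm run)."""
    cols = ["run", "rules_added", "rules_total", "total_weight", "train_accuracy"]
    lines = ["\t".join(cols)]
    for rec in rs.history:
        lines.append("\t".join(f"{rec[c]:.10g}" if isinstance(rec[c], float) else str(rec[c]) for c in cols))
    return "\n".join(lines) + "\n"
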