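"""Rule-edit algebra and the discrete particle swarm over rule sets.

A particle's "position" is a set of B candidate fuzzy rules; its "velocity"
is, per rule slot, a *RAM sequence* — an ordered list of antecedent
substitutions RAM(k, A) that rewrite position k of a rule to symbol A.  The
difference of two rules is the minimal such sequence (BRAMS, one substitution
per differing position), sequences compose by concatenation reduced to basic
form (later substitutions at a position override earlier ones), and a scalar
coefficient acts on a sequence by independent Bernoulli retention of its
operators.  This gives the classical velocity update

    V(T+1) = w x V(T)  (+)  c1 x (Lbest - r)  (+)  c2 x (Gbest - r)

a direct combinatorial meaning.  Each iteration re-derives every candidate
rule's consequent and certainty factor from the training data, prunes rules
whose covered misclassified weight exceeds their covered correct weight
(the g score), and scores a particle by the weighted winner-rule accuracy of
its surviving rules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Hashable, Sequence

import numpy as np

from .boosting import WeightedDataset
from .fuzzy_core import (
    ALPHABET,
    DC_CODE,
    SYMBOLS,
    FuzzyRule,
    FuzzySymbol,
    compatibility_from_codes,
    rule_from_codes,
    winner_indices,
)

N_SYMBOLS = len(ALPHABET)


class DegenerateDataError(ValueError):
    """Swarm search requires at least two classes and positive total weight."""


@dataclass(frozen=True)
class RAMOp:
    """Substitute the antecedent at 1-based ``position`` with ``new_symbol``."""

    position: int
    new_symbol: FuzzySymbol

    def __post_init__(self) -> None:
        if self.position < 1:
            raise IndexError(f"RAM position must be >= 1, got {self.position}")


@dataclass(frozen=True)
class RAMSequence:
    """An ordered list of RAM operators, applied left to right."""

    ops: tuple[RAMOp, ...] = ()

    def __len__(self) -> int:
        return len(self.ops)

    def __iter__(self):
        return iter(self.ops)

    def to_basic(self) -> "RAMSequence":
        """Reduce to basic form: at most one operator per position, keeping
        the last (it is the one that survives sequential application)."""
        last: dict[int, RAMOp] = {}
        order: list[int] = []
        for op in self.ops:
            if op.position not in last:
                order.append(op.position)
            last[op.position] = op
        return RAMSequence(tuple(last[p] for p in order))

    @property
    def is_basic(self) -> bool:
        positions = [op.position for op in self.ops]
        return len(positions) == len(set(positions))


def apply_ram(rule: FuzzyRule, op: RAMOp) -> FuzzyRule:
    """A copy of ``rule`` with the antecedent at ``op.position`` replaced."""
    if not (1 <= op.position <= rule.n_attributes):
        raise IndexError(f"RAM position {op.position} out of range 1..{rule.n_attributes}")
    ant = list(rule.antecedents)
    ant[op.position - 1] = op.new_symbol
    return rule.replace(antecedents=tuple(ant))


def apply_rams(rule: FuzzyRule, seq: RAMSequence) -> FuzzyRule:
    """Apply every operator of ``seq`` to ``rule`` in list order."""
    for op in seq:
        rule = apply_ram(rule, op)
    return rule


def merge(a: RAMSequence, b: RAMSequence) -> RAMSequence:
    """Compose two sequences (a then b) and reduce to basic form; the result
    acts on any rule exactly as the concatenation does."""
    return RAMSequence(a.ops + b.ops).to_basic()


def brams(from_rule: FuzzyRule, to_rule: FuzzyRule) -> RAMSequence:
    """The minimal (basic) sequence turning ``from_rule`` into ``to_rule``:
    one substitution per differing antecedent position."""
    if from_rule.n_attributes != to_rule.n_attributes:
        raise ValueError("antecedent length mismatch")
    ops = tuple(
        RAMOp(k + 1, b)
        for k, (a, b) in enumerate(zip(from_rule.antecedents, to_rule.antecedents))
        if a != b
    )
    return RAMSequence(ops)


def scale_rams(c: float, seq: RAMSequence, rng: np.random.Generator) -> RAMSequence:
    """Coefficient-times-sequence: retain each operator independently with
    probability ``c``, preserving order (so the expected length is c·|seq|).
    ``c`` outside [0, 1] is clamped with a warning."""
    if not 0.0 <= c <= 1.0:
        warnings.warn(f"RAMS coefficient {c} clamped to [0, 1]", stacklevel=2)
        c = min(1.0, max(0.0, c))
    if c == 1.0:
        return seq
    if c == 0.0 or len(seq) == 0:
        return RAMSequence()
    keep = rng.random(len(seq)) < c
    return RAMSequence(tuple(op for op, k in zip(seq.ops, keep) if k))


# ---------------------------------------------------------------------------
# integer-coded kernels (the swarm works on alphabet-index arrays)


def _brams_codes(a: np.ndarray, b: np.ndarray) -> list[tuple[int, int]]:
    diff = np.nonzero(a != b)[0]
    return [(int(k), int(b[k])) for k in diff]


def _scale_ops(c: float, ops: list[tuple[int, int]], rng: np.random.Generator) -> list[tuple[int, int]]:
    if not ops or c <= 0.0:
        return []
    if c >= 1.0:
        return list(ops)
    keep = rng.random(len(ops)) < c
    return [op for op, k in zip(ops, keep) if k]


def _merge_ops(*seqs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    last: dict[int, tuple[int, int]] = {}
    order: list[int] = []
    for seq in seqs:
        for op in seq:
            if op[0] not in last:
                order.append(op[0])
            last[op[0]] = op
    return [last[p] for p in order]


def _apply_ops(codes: np.ndarray, ops: list[tuple[int, int]]) -> None:
    for k, s in ops:
        codes[k] = s


@dataclass
class SwarmConfig:
    """Swarm search parameters; the defaults are the reference configuration
    (swarm of 25 particles, B = 20 rule slots, inertia 1/iteration, random
    acceleration coefficients, stop after 5 stalled iterations)."""

    swarm_size: int = 25
    n_rules: int = 20  # B: candidate rules per particle
    g_threshold: float = 1.0
    stall_limit: int = 5
    max_iters: int = 200
    dc_prob: float = 0.8  # don't-care probability in initial rule strings
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.swarm_size < 2:
            raise ValueError("swarm_size must be >= 2")
        if self.n_rules < 1:
            raise ValueError("n_rules (B) must be >= 1")
        if self.stall_limit < 1:
            raise ValueError("stall_limit must be >= 1")
        if not 0.0 <= self.dc_prob < 1.0:
            raise ValueError("dc_prob must be in [0, 1)")

    @classmethod
    def from_dict(cls, d: dict) -> "SwarmConfig":
        known = {
            k: d[k]
            for k in ("swarm_size", "n_rules", "g_threshold", "stall_limit", "max_iters", "dc_prob", "rng_seed")
            if k in d
        }
        return cls(**known)


@dataclass
class Particle:
    """One candidate rule set: B rules (as alphabet-index code rows), their
    pruning scores and velocities, and the particle's best-ever position."""

    codes: np.ndarray  # (B, n) int
    g: np.ndarray  # (B,)
    velocity: list[list[tuple[int, int]]]  # per slot, list of (0-based pos, code)
    best_codes: np.ndarray | None = None
    best_fitness: float = -np.inf


def g_score(rule: FuzzyRule, data: WeightedDataset) -> float:
    """Pruning score: covered misclassified weight over covered correctly
    classified weight (coverage = strictly positive compatibility).  Returns
    +inf when the rule covers no weight of its own class."""
    mu = data.compatibility(rule)
    covered = mu > 0.0
    match = data.labels == rule.consequent
    ncp = float(data.weights[covered & match].sum())
    nmp = float(data.weights[covered & ~match].sum())
    if ncp == 0.0:
        return np.inf
    return nmp / ncp


def particle_fitness(rules: Sequence[FuzzyRule], data: WeightedDataset) -> float:
    """Weighted winner-rule training accuracy of a rule set (unclassified
    counts as wrong).  ``rules`` should already be the acceptable subset."""
    total = data.total_weight
    if total <= 0.0:
        raise DegenerateDataError("total instance weight is zero")
    if not rules:
        return 0.0
    classes = data.classes
    cidx = {h: i for i, h in enumerate(classes)}
    codes = np.stack([r.codes() for r in rules])
    cons = np.array([cidx[r.consequent] for r in rules], dtype=np.int64)
    cfs = np.array([r.cf for r in rules])
    products = compatibility_from_codes(codes, data.membership_table()) * cfs[:, None]
    win = winner_indices(products, cons)
    y = np.array([cidx[l] for l in data.labels], dtype=np.int64)
    return float((data.weights * (win == y)).sum() / total)


class _SwarmState:
    """Vectorised evaluation context for one pso_run."""

    def __init__(self, data: WeightedDataset):
        self.classes = data.classes
        if len(self.classes) < 2:
            raise DegenerateDataError("swarm search needs at least two classes")
        self.table = data.membership_table()
        cidx = {h: i for i, h in enumerate(self.classes)}
        self.y = np.array([cidx[l] for l in data.labels], dtype=np.int64)
        self.c = len(self.classes)
        self.onehot = np.zeros((len(data), self.c))
        self.onehot[np.arange(len(data)), self.y] = 1.0
        self.counts = self.onehot.sum(axis=0)
        if (self.counts == 0).any():  # pragma: no cover - classes come from labels
            raise DegenerateDataError("empty class")
        self.w = data.weights
        self.total_w = float(self.w.sum())
        if self.total_w <= 0.0:
            raise DegenerateDataError("total instance weight is zero")
        self.weighted_onehot = self.onehot * self.w[:, None]

    def evaluate_rules(self, codes: np.ndarray):
        """Consequents, CFs, g scores and compatibilities for coded rules.

        ``codes`` is (R, n).  Returns (mu (R, m), cons (R,), cf (R,), g (R,)).
        Vacuous rules (all-zero or tied beta) get cons = -1, cf = 0.
        """
        mu = compatibility_from_codes(codes, self.table)
        sums = mu @ self.onehot  # (R, c)
        beta = sums / self.counts[None, :]
        total = beta.sum(axis=1)
        order = np.argsort(-beta, axis=1)
        best = np.take_along_axis(beta, order[:, :1], axis=1)[:, 0]
        second = np.take_along_axis(beta, order[:, 1:2], axis=1)[:, 0]
        cons = order[:, 0].astype(np.int64)
        vacuous = (total <= 0.0) | (best == second)
        with np.errstate(invalid="ignore", divide="ignore"):
            cf = (best - (total - best) / (self.c - 1)) / total
        cf = np.where(vacuous, 0.0, cf)
        cons = np.where(vacuous, -1, cons)
        # g score on the boosting weights, restricted to covered instances
        covered = (mu > 0.0).astype(float)
        cw = covered @ self.weighted_onehot  # (R, c) covered weight per class
        ncp = np.take_along_axis(cw, np.maximum(cons, 0)[:, None], axis=1)[:, 0]
        nmp = cw.sum(axis=1) - ncp
        with np.errstate(invalid="ignore", divide="ignore"):
            g = np.where(ncp > 0.0, nmp / np.where(ncp > 0.0, ncp, 1.0), np.inf)
        return mu, cons, cf, g

    def fitness(self, mu: np.ndarray, cons: np.ndarray, cf: np.ndarray, acceptable: np.ndarray) -> float:
        if not acceptable.any():
            return 0.0
        products = mu[acceptable] * cf[acceptable, None]
        win = winner_indices(products, cons[acceptable])
        return float((self.w * (win == self.y)).sum() / self.total_w)


def _random_velocity(n: int, rng: np.random.Generator) -> list[tuple[int, int]]:
    length = int(rng.integers(0, n + 1))
    if length == 0:
        return []
    positions = rng.choice(n, size=length, replace=False)
    symbols = rng.integers(0, N_SYMBOLS, size=length)
    return [(int(p), int(s)) for p, s in zip(positions, symbols)]


def _random_codes(B: int, n: int, dc_prob: float, rng: np.random.Generator) -> np.ndarray:
    """Random rule strings with a don't-care bias: each position is DC with
    probability ``dc_prob``, otherwise uniform over the 14 fuzzy sets.  The
    bias keeps initial rules general (short); without it random strings are
    almost surely maximally specific conjunctions that cover nothing, and the
    edit moves toward swarm bests can only exchange specific symbols, never
    shorten rules."""
    dc = rng.random((B, n)) < dc_prob
    sym = rng.integers(1, N_SYMBOLS, size=(B, n))
    return np.where(dc, 0, sym)


def pso_run(data: WeightedDataset, cfg: SwarmConfig, rng: np.random.Generator) -> list[FuzzyRule]:
    """One discrete-PSO search; returns the global best particle's acceptable
    rules (g <= threshold, CF > 0), deduplicated, as :class:`FuzzyRule`.

    Particles start from random symbol strings (don't-care-biased, see
    :func:`_random_codes`) with random velocities; every iteration
    re-derives consequents/CFs, updates personal
    and global bests, and moves each rule slot by the merged, coefficient-
    scaled edit sequences toward the personal and global bests.  Stops when
    the global best fitness has not improved for ``stall_limit`` consecutive
    iterations (or at ``max_iters``).
    """
    state = _SwarmState(data)
    n = data.n_attributes
    B = cfg.n_rules
    L = cfg.swarm_size

    particles = [
        Particle(
            codes=_random_codes(B, n, cfg.dc_prob, rng),
            g=rng.random(B),
            velocity=[_random_velocity(n, rng) for _ in range(B)],
        )
        for _ in range(L)
    ]

    gbest_fitness = -np.inf
    gbest_codes: np.ndarray | None = None
    gbest_rules: list[tuple[tuple[int, ...], int, float]] = []
    stall = 0

    for iteration in range(1, cfg.max_iters + 1):
        all_codes = np.concatenate([p.codes for p in particles], axis=0)
        mu, cons, cf, g = state.evaluate_rules(all_codes)

        improved = False
        for h, p in enumerate(particles):
            sl = slice(h * B, (h + 1) * B)
            p.g = g[sl]
            acceptable = (p.g <= cfg.g_threshold) & (cf[sl] > 0.0) & (cons[sl] >= 0)
            fit = state.fitness(mu[sl], cons[sl], cf[sl], acceptable)
            if fit > p.best_fitness:
                p.best_fitness = fit
                p.best_codes = p.codes.copy()
            if fit > gbest_fitness:
                gbest_fitness = fit
                gbest_codes = p.codes.copy()
                idx = np.nonzero(acceptable)[0]
                gbest_rules = [
                    (tuple(int(c) for c in p.codes[j]), int(cons[sl][j]), float(cf[sl][j]))
                    for j in idx
                ]
                improved = True

        stall = 0 if improved else stall + 1
        if stall >= cfg.stall_limit:
            break

        omega = min(1.0, 1.0 / iteration)
        c1 = float(rng.random())
        c2 = float(rng.random())
        for p in particles:
            lbest = p.best_codes if p.best_codes is not None else p.codes
            for j in range(B):
                inertia = _scale_ops(omega, p.velocity[j], rng)
                toward_local = _scale_ops(c1, _brams_codes(p.codes[j], lbest[j]), rng)
                toward_global = (
                    _scale_ops(c2, _brams_codes(p.codes[j], gbest_codes[j]), rng)
                    if gbest_codes is not None
                    else []
                )
                v = _merge_ops(inertia, toward_local, toward_global)
                p.velocity[j] = v
                _apply_ops(p.codes[j], v)

    # deduplicate the stored best snapshot by (antecedent string, class)
    seen: set[tuple[tuple[int, ...], int]] = set()
    out: list[FuzzyRule] = []
    for codes, cons_i, cf_v in gbest_rules:
        key = (codes, cons_i)
        if key in seen:
            continue
        seen.add(key)
        out.append(rule_from_codes(codes, state.classes[cons_i], cf_v))
    return out
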