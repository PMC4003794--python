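"""Fuzzy partitions, rule representation and single-winner inference.

The classifier works on the unit hypercube: every attribute of a record is
scaled into [0, 1] and matched against one of 14 symmetric triangular fuzzy
sets drawn from four uniform (Ruspini) partitions of granularity 2-5, plus a
"don't care" wildcard.  A rule is a conjunction of such sets, one per
attribute, with a consequent class and a certainty factor (CF) computed from
the class-wise compatibility of the training data.  Classification picks the
single rule maximising ``compatibility x CF`` ("winner rule").

Rules are encoded as strings over a 15-symbol alphabet::

    0 = don't care
    1 2           = S2 L2          (granularity 2)
    3 4 5         = S3 M3 L3       (granularity 3)
    6 7 8 9       = S4 MS4 ML4 L4  (granularity 4)
    a b c d e     = S5 MS5 M5 ML5 L5  (granularity 5)

e.g. ``"0150b0"`` reads "if x2 is S2 and x3 is L3 and x5 is MS5".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Sequence

import numpy as np

ALPHABET = "0123456789abcde"
DC_CODE = "0"

#: code -> (granularity K, 1-based index within the partition)
_CODE_TO_PART: dict[str, tuple[int, int]] = {}
_PART_TO_CODE: dict[tuple[int, int], str] = {}
_next = 1
for _K in (2, 3, 4, 5):
    for _i in range(1, _K + 1):
        _code = ALPHABET[_next]
        _next += 1
        _CODE_TO_PART[_code] = (_K, _i)
        _PART_TO_CODE[(_K, _i)] = _code

#: human-readable linguistic names, e.g. "MS5" = medium-small of granularity 5
_PART_NAMES = {2: ("S", "L"), 3: ("S", "M", "L"), 4: ("S", "MS", "ML", "L"), 5: ("S", "MS", "M", "ML", "L")}


class InvalidSymbolError(ValueError):
    """A character outside the 15-symbol rule alphabet."""


class RuleVacuousError(ValueError):
    """A rule with zero compatibility to every training instance (or an
    ambiguous consequent); such rules are rejected."""


class DegenerateClassError(ValueError):
    """Training data with an empty class where a per-class sum is required."""


@dataclass(frozen=True)
class FuzzySymbol:
    """One antecedent fuzzy set (or the don't-care wildcard)."""

    code: str

    def __post_init__(self) -> None:
        if len(self.code) != 1 or self.code not in ALPHABET:
            raise InvalidSymbolError(f"not a rule-alphabet symbol: {self.code!r}")

    @property
    def is_dc(self) -> bool:
        return self.code == DC_CODE

    @property
    def granularity(self) -> int | None:
        return None if self.is_dc else _CODE_TO_PART[self.code][0]

    @property
    def index(self) -> int | None:
        return None if self.is_dc else _CODE_TO_PART[self.code][1]

    @property
    def name(self) -> str:
        if self.is_dc:
            return "DC"
        K, i = _CODE_TO_PART[self.code]
        return f"{_PART_NAMES[K][i - 1]}{K}"

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"FuzzySymbol({self.code!r}:{self.name})"


#: the full alphabet, keyed by code
SYMBOLS: dict[str, FuzzySymbol] = {c: FuzzySymbol(c) for c in ALPHABET}


def symbol(granularity: int, index: int) -> FuzzySymbol:
    """The symbol for partition ``granularity`` set ``index`` (1-based)."""
    try:
        return SYMBOLS[_PART_TO_CODE[(granularity, index)]]
    except KeyError:
        raise InvalidSymbolError(f"no fuzzy set ({granularity}, {index})") from None


def membership(sym: FuzzySymbol, x: float | None) -> float:
    """Membership of scaled value ``x`` in the fuzzy set ``sym``.

    Set ``i`` of granularity ``K`` is a symmetric triangle with apex at
    ``(i-1)/(K-1)`` falling linearly to 0 at distance ``1/(K-1)``; the K
    triangles of one granularity sum to 1 everywhere on [0, 1].  Don't-care
    and missing values (``None``/NaN) give membership 1.
    """
    if sym.is_dc:
        return 1.0
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return 1.0
    K, i = _CODE_TO_PART[sym.code]
    apex = (i - 1) / (K - 1)
    return max(0.0, 1.0 - abs(x - apex) * (K - 1))


@dataclass(frozen=True)
class FuzzyRule:
    """A fuzzy if-then rule: antecedent fuzzy sets, consequent class, CF."""

    antecedents: tuple[FuzzySymbol, ...]
    consequent: Hashable
    cf: float = 1.0

    @property
    def n_attributes(self) -> int:
        return len(self.antecedents)

    @property
    def length(self) -> int:
        """Number of active (non-don't-care) antecedents."""
        return sum(1 for s in self.antecedents if not s.is_dc)

    def encode(self) -> str:
        return "".join(s.code for s in self.antecedents)

    def codes(self) -> np.ndarray:
        """Antecedents as an int array of alphabet indices (0 = DC)."""
        return np.fromiter((ALPHABET.index(s.code) for s in self.antecedents), dtype=np.int64, count=len(self.antecedents))

    def replace(self, **kw) -> "FuzzyRule":
        d = {"antecedents": self.antecedents, "consequent": self.consequent, "cf": self.cf}
        d.update(kw)
        return FuzzyRule(**d)


def encode(rule: FuzzyRule) -> str:
    """The rule's antecedent string over the 15-symbol alphabet."""
    return rule.encode()


def decode(s: str, consequent: Hashable, cf: float = 1.0) -> FuzzyRule:
    """Parse an antecedent string; raises :class:`InvalidSymbolError` on an
    illegal character."""
    return FuzzyRule(tuple(SYMBOLS[c] if c in SYMBOLS else _bad(c) for c in s), consequent, cf)


def _bad(c: str):
    raise InvalidSymbolError(f"illegal rule character {c!r}")


def rule_from_codes(codes: Sequence[int], consequent: Hashable, cf: float = 1.0) -> FuzzyRule:
    return FuzzyRule(tuple(SYMBOLS[ALPHABET[int(c)]] for c in codes), consequent, cf)


@dataclass
class Instance:
    """One record: scaled attribute values (NaN = missing), class label,
    boosting weight."""

    values: np.ndarray
    label: Hashable
    weight: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.weight < 0:
            raise ValueError("instance weight must be nonnegative")
        ok = np.isnan(self.values) | ((self.values >= 0) & (self.values <= 1))
        if not ok.all():
            raise ValueError("non-missing attribute values must lie in [0, 1]")


def rule_compatibility(rule: FuzzyRule, instance: Instance | np.ndarray) -> float:
    """Compatibility of an instance with a rule: the product of per-attribute
    memberships."""
    values = instance.values if isinstance(instance, Instance) else np.asarray(instance, float)
    if len(values) != rule.n_attributes:
        raise ValueError(f"instance has {len(values)} attributes, rule expects {rule.n_attributes}")
    out = 1.0
    for sym, x in zip(rule.antecedents, values):
        out *= membership(sym, float(x))
        if out == 0.0:
            break
    return out


@dataclass
class ClassCompatibility:
    """Per-class relative compatibility sums beta_h and class sizes."""

    beta: dict[Hashable, float]
    counts: dict[Hashable, int]


def class_compatibility(rule: FuzzyRule, data: Iterable[Instance]) -> ClassCompatibility:
    """beta_h = (sum of compatibilities over class-h instances) / N_h."""
    sums: dict[Hashable, float] = {}
    counts: dict[Hashable, int] = {}
    for inst in data:
        mu = rule_compatibility(rule, inst)
        sums[inst.label] = sums.get(inst.label, 0.0) + mu
        counts[inst.label] = counts.get(inst.label, 0) + 1
    if not counts:
        raise DegenerateClassError("empty training data")
    beta = {h: sums[h] / counts[h] for h in counts}
    return ClassCompatibility(beta=beta, counts=counts)


def certainty_factor(beta: ClassCompatibility) -> tuple[Hashable, float]:
    """Consequent class and certainty factor from class compatibilities.

    The consequent is the class with maximal beta; the CF discounts the
    winner's share by the mean of the other classes::

        CF = (beta_win - sum(beta_other) / (c - 1)) / sum(beta)

    Raises :class:`RuleVacuousError` when all beta are zero.  A tied argmax
    (e.g. balanced beta) gives CF = 0 with the first class in sorted order,
    so the rule is rejected downstream: rules without positive CF are never
    stored.
    """
    items = sorted(beta.beta.items(), key=lambda kv: str(kv[0]))
    total = sum(v for _, v in items)
    if total <= 0.0:
        raise RuleVacuousError("rule has zero compatibility with every class")
    best = max(v for _, v in items)
    winners = [h for h, v in items if v == best]
    winner = winners[0]
    c = len(items)
    if len(winners) > 1:
        return winner, 0.0
    others = total - best
    cf = (best - others / (c - 1)) / total if c > 1 else best / total
    return winner, cf


def classify(rules: Sequence[FuzzyRule], instance: Instance | np.ndarray):
    """Single-winner classification: the consequent of the rule maximising
    ``compatibility x CF``.

    Returns ``None`` (unclassified) for an empty rule set, when no rule has a
    positive product, or when rules of different classes tie for the maximum.
    """
    best = 0.0
    winner = None
    ambiguous = False
    for r in rules:
        p = rule_compatibility(r, instance) * r.cf
        if p > best:
            best, winner, ambiguous = p, r.consequent, False
        elif p == best and p > 0.0 and r.consequent != winner:
            ambiguous = True
    if best <= 0.0 or ambiguous:
        return None
    return winner


# ---------------------------------------------------------------------------
# vectorised kernels shared by the swarm search and batch prediction


def membership_table(X: np.ndarray) -> np.ndarray:
    """Memberships of every alphabet symbol for every attribute value.

    Returns an array of shape ``(15, n_attributes, n_instances)``; missing
    values (NaN) and the don't-care row are 1 everywhere.
    """
    X = np.asarray(X, dtype=float)
    m, n = X.shape
    tab = np.ones((len(ALPHABET), n, m))
    Xt = X.T
    nanmask = np.isnan(Xt)
    Xf = np.where(nanmask, 0.5, Xt)
    for s, code in enumerate(ALPHABET[1:], start=1):
        K, i = _CODE_TO_PART[code]
        apex = (i - 1) / (K - 1)
        mu = np.maximum(0.0, 1.0 - np.abs(Xf - apex) * (K - 1))
        mu[nanmask] = 1.0
        tab[s] = mu
    return tab


def compatibility_from_codes(codes: np.ndarray, table: np.ndarray) -> np.ndarray:
    """Compatibility vectors for encoded rules against a membership table.

    ``codes`` is ``(..., n)`` int (alphabet indices); returns ``(..., m)``.
    """
    codes = np.asarray(codes)
    n = codes.shape[-1]
    return table[codes, np.arange(n), :].prod(axis=-2)


def winner_indices(products: np.ndarray, consequent_idx: np.ndarray) -> np.ndarray:
    """Winner-rule class indices for a product matrix.

    ``products`` is ``(R, m)`` (compatibility x CF per rule per instance),
    ``consequent_idx`` ``(R,)`` int class indices.  Returns ``(m,)`` class
    indices, with ``-1`` for unclassified instances (no positive product, or a
    tie between rules of different classes).
    """
    m = products.shape[1]
    if products.shape[0] == 0:
        return np.full(m, -1, dtype=np.int64)
    best = products.max(axis=0)
    iswin = products == best[None, :]
    ci = consequent_idx[:, None]
    wmin = np.where(iswin, ci, np.iinfo(np.int64).max).min(axis=0)
    wmax = np.where(iswin, ci, np.int64(-1)).max(axis=0)
    return np.where((best > 0) & (wmin == wmax), wmax, np.int64(-1))


def classify_batch(rules: Sequence[FuzzyRule], X: np.ndarray, table: np.ndarray | None = None) -> list:
    """Winner-rule classification of every row of ``X``; ``None`` entries mark
    unclassified instances."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if not rules:
        return [None] * X.shape[0]
    n = X.shape[1]
    for r in rules:
        if r.n_attributes != n:
            raise ValueError("rule/attribute-count mismatch")
    if table is None:
        table = membership_table(X)
    codes = np.stack([r.codes() for r in rules])
    classes = sorted({r.consequent for r in rules}, key=str)
    cidx = {h: i for i, h in enumerate(classes)}
    cons = np.array([cidx[r.consequent] for r in rules], dtype=np.int64)
    cfs = np.array([r.cf for r in rules])
    products = compatibility_from_codes(codes, table) * cfs[:, None]
    win = winner_indices(products, cons)
    return [classes[i] if i >= 0 else None for i in win]
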