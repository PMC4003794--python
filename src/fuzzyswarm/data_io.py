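"""Reading UCI-layout heart-disease records and generating synthetic data.

The supported on-disk dialect is the "processed" UCI heart-disease layout:
14 comma-separated fields per record (13 predictors + the ``num`` outcome),
``?`` for a missing value.  ``num`` counts angiographically narrowed vessels
(0-4) and is binarised here: 0 -> "healthy", 1-4 -> "patient" (these strings
are used internally because the numeric 0/1 polarity is ambiguous across
sources).  Categorical predictors (chest-pain type, rest ECG, slope, thal,
...) are kept as their integer codes; all predictors are min-max scaled into
[0, 1], missing values stay missing.

The synthetic generator draws instances uniformly on the unit hypercube and
labels them by winner-rule inference over a small set of planted fuzzy rules
(CF fixed at 1 during generation), optionally flipping a fraction of labels;
it returns the ground-truth rules so recovery can be scored.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Hashable, Sequence

import numpy as np
import pandas as pd
from sklearn.preprocessing import MinMaxScaler

from .fuzzy_core import FuzzyRule, Instance, classify_batch, decode, rule_compatibility

UCI_ATTRIBUTES = [
    "age", "sex", "cp", "trestbps", "chol", "fbs", "restecg",
    "thalach", "exang", "oldpeak", "slope", "ca", "thal",
]
UCI_OUTCOME = "num"
HEALTHY, PATIENT = "healthy", "patient"

#: attribute kinds in the 13-predictor schema
_CATEGORICAL = {"sex", "cp", "fbs", "restecg", "exang", "slope", "thal"}


class FormatError(ValueError):
    """Malformed input record (wrong field count or unparseable token)."""


class SpecError(ValueError):
    """An unsatisfiable synthetic-data specification."""


@dataclass
class AttributeSchema:
    """Name, kind and observed scaling range of one predictor."""

    name: str
    kind: str  # "numeric" | "categorical-coded"
    min: float
    max: float


def _validate_field_counts(text: str, expected: int = 14) -> None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        nfields = line.count(",") + 1
        if nfields != expected:
            raise FormatError(f"line {lineno}: expected {expected} comma-separated fields, found {nfields}")


def load_uci_frame(path_or_text) -> tuple[pd.DataFrame, np.ndarray]:
    """Raw (unscaled) predictor frame and binary labels from a UCI file.

    Accepts a path or a file-like object.  Predictors keep NaN for ``?``;
    labels are the strings "healthy" (num == 0) / "patient" (num in 1-4).
    """
    if hasattr(path_or_text, "read"):
        text = path_or_text.read()
    else:
        with open(path_or_text) as fh:
            text = fh.read()
    _validate_field_counts(text)
    try:
        df = pd.read_csv(
            io.StringIO(text),
            header=None,
            names=UCI_ATTRIBUTES + [UCI_OUTCOME],
            na_values="?",
            skipinitialspace=True,
        )
        df = df.apply(pd.to_numeric)
    except ValueError as e:
        raise FormatError(f"unparseable numeric field: {e}") from e
    num = df.pop(UCI_OUTCOME)
    if num.isna().any():
        raise FormatError("missing outcome (num) field")
    labels = np.where(num.to_numpy() == 0, HEALTHY, PATIENT).astype(object)
    return df, labels


def scale_frame(
    train: pd.DataFrame, test: pd.DataFrame | None = None
) -> tuple[np.ndarray, np.ndarray | None, list[AttributeSchema]]:
    """Min-max scale predictors into [0, 1] using the training frame's
    observed ranges (test values are clipped); NaN propagates.  A constant
    column maps to 0.5."""
    scaler = MinMaxScaler(clip=True)
    Xtr = scaler.fit_transform(train.to_numpy(dtype=float))
    constant = scaler.data_max_ == scaler.data_min_
    if constant.any():
        Xtr[:, constant] = np.where(np.isnan(Xtr[:, constant]), np.nan, 0.5)
    Xte = None
    if test is not None:
        Xte = scaler.transform(test.to_numpy(dtype=float))
        if constant.any():
            Xte[:, constant] = np.where(np.isnan(Xte[:, constant]), np.nan, 0.5)
    schema = [
        AttributeSchema(
            name=c,
            kind="categorical-coded" if c in _CATEGORICAL else "numeric",
            min=float(mn),
            max=float(mx),
        )
        for c, mn, mx in zip(train.columns, scaler.data_min_, scaler.data_max_)
    ]
    return Xtr, Xte, schema


def unscale(X: np.ndarray, schema: Sequence[AttributeSchema]) -> np.ndarray:
    """Invert :func:`scale_frame` (within numeric tolerance)."""
    X = np.asarray(X, dtype=float)
    mins = np.array([a.min for a in schema])
    maxs = np.array([a.max for a in schema])
    span = np.where(maxs > mins, maxs - mins, 0.0)
    return X * span + mins


def read_uci(path_or_text) -> tuple[list[Instance], list[AttributeSchema]]:
    """Parse, binarise and scale a UCI-layout file into classifier-ready
    instances (scaling ranges observed on this file)."""
    df, labels = load_uci_frame(path_or_text)
    X, _, schema = scale_frame(df)
    return [Instance(x, l) for x, l in zip(X, labels)], schema


def write_uci(path, X_raw: np.ndarray, labels: Sequence[Hashable]) -> None:
    """Write records back in the same comma-separated dialect (``?`` for
    missing; labels mapped healthy -> 0, patient -> 1)."""
    with open(path, "w") as fh:
        for row, lab in zip(np.asarray(X_raw, dtype=float), labels):
            fields = ["?" if np.isnan(v) else f"{v:g}" for v in row]
            fields.append("0" if lab == HEALTHY else "1")
            fh.write(",".join(fields) + "\n")


# ---------------------------------------------------------------------------
# synthetic planted-rule data


@dataclass
class SyntheticSpec:
    """Specification of a planted-rule dataset on [0, 1]^n.

    ``rules`` are the ground truth (their CFs are forced to 1 for labeling);
    ``fallback_class`` labels instances no rule covers; labels are flipped to
    a uniformly random other class with probability ``noise_rate``.
    """

    n_attributes: int
    n_instances: int
    rules: list[FuzzyRule]
    noise_rate: float = 0.0
    fallback_class: Hashable = None
    overlap_threshold: float = 0.25

    def __post_init__(self) -> None:
        if not 0.0 <= self.noise_rate < 0.5:
            raise SpecError("noise_rate must be in [0, 0.5)")
        if self.n_instances < 0:
            raise SpecError("n_instances must be nonnegative")
        for r in self.rules:
            if r.n_attributes != self.n_attributes:
                raise SpecError("planted rule length != n_attributes")
        self._check_disjoint()
        if self.fallback_class is None and self.rules:
            self.fallback_class = self.rules[-1].consequent

    def _apex_point(self, rule: FuzzyRule) -> np.ndarray:
        """The point of maximal compatibility (0.5 at don't-care positions)."""
        x = np.full(self.n_attributes, 0.5)
        for i, s in enumerate(rule.antecedents):
            if not s.is_dc:
                x[i] = (s.index - 1) / (s.granularity - 1)
        return x

    def _check_disjoint(self) -> None:
        for i, a in enumerate(self.rules):
            for b in self.rules[i + 1 :]:
                if a.consequent == b.consequent:
                    continue
                overlap = max(
                    rule_compatibility(b, self._apex_point(a)),
                    rule_compatibility(a, self._apex_point(b)),
                )
                if overlap >= self.overlap_threshold:
                    raise SpecError(
                        f"planted rules {a.encode()} and {b.encode()} overlap "
                        f"(apex compatibility {overlap:.3f} >= {self.overlap_threshold})"
                    )


def generate_synthetic(spec: SyntheticSpec, rng: np.random.Generator) -> tuple[list[Instance], list[FuzzyRule]]:
    """Draw ``spec.n_instances`` uniform instances labeled by the planted
    rules (winner-rule inference, CF = 1), then apply label noise.  Returns
    (instances, ground-truth rules)."""
    truth = [r.replace(cf=1.0) for r in spec.rules]
    X = rng.random((spec.n_instances, spec.n_attributes))
    if spec.n_instances == 0:
        return [], truth
    labels = classify_batch(truth, X)
    labels = [spec.fallback_class if l is None else l for l in labels]
    classes = sorted({r.consequent for r in truth} | {spec.fallback_class}, key=str)
    if spec.noise_rate > 0.0 and len(classes) > 1:
        flip = rng.random(spec.n_instances) < spec.noise_rate
        for k in np.nonzero(flip)[0]:
            others = [c for c in classes if c != labels[k]]
            labels[k] = others[int(rng.integers(len(others)))]
    return [Instance(x, l) for x, l in zip(X, labels)], truth


def planted_two_rule_spec(n_instances: int = 200, noise_rate: float = 0.05) -> SyntheticSpec:
    """The reference recovery benchmark: 5 attributes, two disjoint planted
    2-antecedent rules splitting the unit square diagonally (three nuisance
    attributes are pure noise)."""
    rules = [
        decode("11000", "pos"),  # x1 small, x2 small (granularity 2)
        decode("22000", "neg"),  # x1 large, x2 large
    ]
    return SyntheticSpec(
        n_attributes=5,
        n_instances=n_instances,
        rules=rules,
        noise_rate=noise_rate,
        fallback_class="neg",
    )


def write_synthetic_csv(path, instances: Sequence[Instance]) -> None:
    """Plain CSV: one column per attribute plus a final ``label`` column."""
    n = instances[0].values.shape[0] if instances else 0
    df = pd.DataFrame(
        [list(i.values) + [i.label] for i in instances],
        columns=[f"x{j+1}" for j in range(n)] + ["label"],
    )
    df.to_csv(path, index=False, float_format="%.10g")


def read_synthetic_csv(path) -> list[Instance]:
    df = pd.read_csv(path)
    labels = df.pop("label").astype(str).to_numpy(dtype=object)
    X = df.to_numpy(dtype=float)
    return [Instance(x, l) for x, l in zip(X, labels)]
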