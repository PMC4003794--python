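# Methods

## The model

`fuzzyswarm` learns a compact set of fuzzy if-then rules for binary
classification of tabular clinical records. Every attribute is min-max
scaled into [0, 1] and matched against symmetric triangular fuzzy sets drawn
from four uniform Ruspini partitions of granularity K = 2, 3, 4, 5 (set *i*
of granularity *K* has its apex at (i−1)/(K−1) and falls linearly to zero at
distance 1/(K−1); the K sets of one partition sum to 1 everywhere on [0, 1]).
Together with a "don't care" wildcard this gives a 15-symbol alphabet, so a
rule over *n* attributes is an *n*-character string plus a consequent class.

A rule R with antecedent sets A_1 … A_n matches an instance
x = (x_1 … x_n) with *compatibility*

    mu_R(x) = prod_i  mu_{A_i}(x_i)

Don't-care positions and missing values contribute a factor of 1 (a missing
attribute is treated as uninformative rather than imputed). For each rule the
training data determine a per-class relative compatibility

    beta_h(R) = ( sum_{x in class h} mu_R(x) ) / N_h

the consequent class is argmax_h beta_h, and the *certainty factor*

    CF = ( beta_win − mean_{h != win} beta_h ) / sum_h beta_h

lies in [−1, 1] for two classes. A tied argmax yields CF = 0 and the rule is
discarded (only rules with CF > 0 are ever stored). Classification is
single-winner: the predicted class is the consequent of the rule maximising
mu_R(x)·CF; if no rule has a positive product, or rules of different classes
tie exactly, the instance is *unclassified*, which every metric in this
package counts as an error.

## Rule search: a discrete swarm over an edit algebra

Rules are searched by particle swarm optimisation in which the continuous
velocity algebra is replaced by *rule-edit sequences*: a RAM operator
substitutes the antecedent symbol at one position; an ordered sequence of
RAMs is a velocity; the difference of two rules is the minimal (basic)
sequence with one substitution per differing position; sequences compose by
concatenation reduced to basic form (the last substitution at a position
wins); and a scalar coefficient c ∈ [0, 1] acts on a sequence by retaining
each operator independently with probability c, so the expected edit length
scales with c. These definitions make the classical update

    V(T+1) = omega·V(T) ⊕ c1·(Lbest − r) ⊕ c2·(Gbest − r)
    r(T+1) = r(T) + V(T+1)

well defined on rule strings.

A particle is a set of B candidate rules (B = 20 by default) with one
velocity per rule slot. Each iteration re-derives every candidate's
consequent and CF from the training data, computes a pruning score

    g = NMP / NCP

(the covered misclassified weight over the covered correctly-classified
weight, coverage meaning strictly positive compatibility; NCP = 0 gives
g = ∞), and scores the particle by the *weighted winner-rule training
accuracy* of its acceptable rules (g ≤ 1 and CF > 0), with unclassified
instances counted wrong. The swarm objective is therefore exactly the
quantity the boosting loop and the final evaluation care about.

Reference configuration: 25 particles; inertia omega = 1/T (1-based
iteration count, clamped to [0, 1]); c1, c2 ~ U(0, 1) redrawn each
iteration; search stops when the global best has not improved for 5
consecutive iterations (a hard cap of 200 iterations guards the degenerate
case). Ties for the global best go to the earliest particle. The run returns
the global best's acceptable rules, deduplicated by antecedent string and
class.

### Don't-care-biased initialisation

Initial rule strings draw each position as don't-care with probability
`dc_prob` (default 0.8) and otherwise uniformly over the 14 fuzzy sets. This
choice matters: strings drawn uniformly over the full alphabet are almost
surely maximally specific conjunctions that cover essentially no instances,
and because the swarm's moves only copy symbols from personal/global bests,
specificity can never decrease — the search then terminates in large sets of
overfitted five-antecedent rules. The don't-care bias (the standard choice
in genetics-based fuzzy rule learning) starts the search among general,
high-coverage rules and lets it specialise only where the data reward it; it
is what produces rule sets of mean length ~2 on the synthetic benchmark
instead of ~4.6, with materially better held-out accuracy. Initial
velocities are random basic sequences (length uniform on {0..n}, distinct
positions, uniform symbols); initial pruning scores are uniform on [0, 1]
and are recomputed from the data before first use.

## Boosting between runs

All instance weights start at 1. After a swarm run, each returned rule is
appended to the rule set (skipping exact duplicates) and immediately decays
the weights of the instances it classifies correctly:

    ER    = sum_{wrong class} w_k mu(x_k) / sum_k w_k mu(x_k)
    alpha = ( 1 / (1 + exp( mu(x_k) / (ER + w_k) )) )^mu(x_k)
    w_k  <- w_k · alpha     (only when the instance's label equals the
                             rule's consequent; others keep their weight
                             bit-for-bit)

ER is recomputed against the current weights before each rule's update, in
the order the rules were returned. A rule that covers nothing (denominator
zero) has ER = 0 and changes no weight. alpha is strictly decreasing in mu,
so the better an instance is covered, the more its weight shrinks; weights
never increase and there is no floor or renormalisation. The outer loop runs
swarm searches until the total remaining weight drops to K (default 12), a
run cap (50) is hit, or two consecutive runs contribute no new rule — the
latter two are safety guards because multiplicative decay alone cannot
guarantee the threshold is reached when rules stop covering anything.

## Synthetic data

The generator draws instances uniformly on [0, 1]^n and labels them by
winner-rule inference over a small set of planted rules with CF fixed at 1,
assigning a fallback class to uncovered instances and flipping each label to
a random other class with the configured noise rate. Planted rules of
different classes must be region-disjoint: the compatibility of each rule at
the other's apex point must stay below 0.25.

The reference benchmark (`planted_two_rule_spec`) uses 5 attributes, 200
instances, two 2-antecedent granularity-2 rules — "11000" → pos, "22000" →
neg, which split the (x1, x2) unit square along the diagonal while x3–x5 are
pure nuisance — and 5% label noise. Five attributes keeps the search space
representative (15^5 strings) while the noise rate and sample size mirror a
small clinical table. What this benchmark shows: the edit-algebra swarm plus
boosting recovers planted structure from noisy data and generalises to fresh
draws. What it does not show: behaviour under missing values, correlated or
categorical predictors, or class imbalance — real clinical tables have all
of these, and results there depend additionally on the min-max scaling and
the missing-as-don't-care policy.

Under these conditions the intrinsic ceiling on training accuracy is ≈0.95
(the noise rate), and the planted-rule oracle itself scores ≈0.93–0.95; the
learned rule sets typically land at 0.89–0.95 training and 0.84–0.94
held-out accuracy, so the benchmark thresholds (0.90 train / 0.85 held-out)
sit deliberately close to the achievable optimum.

## Numerical and design choices

- **Exact-tie semantics.** Winner-rule ties across classes at equal products
  → unclassified (an error); argmax ties in beta → CF = 0 → rule rejected;
  ties between particles for the global best → earliest particle. All
  comparisons are exact float comparisons; determinism is guaranteed by a
  single seeded generator threaded through every stochastic step.
- **g restricted to covered instances.** Summing the weight of *all*
  instances of the wrong/right class regardless of coverage would make g
  independent of the rule antecedent for fixed weights; the covered reading
  makes it the rule's own error odds.
- **Pruned slots keep moving.** Rules pruned by g still receive velocity
  updates; pruning affects only fitness and the returned set.
- **Empty-coverage conventions.** ER = 0 (no weight change); class
  compatibility all zero → rule rejected; empty rule set → everything
  unclassified; empty-rule-set statistics report (0, 0).
- **Scaling.** Min-max statistics come from training folds only and test
  values are clipped into [0, 1]; a constant column maps to 0.5.
  Categorical codes are scaled like numeric values; no one-hot expansion.
- **Cross-validation.** Stratified k-fold (class proportions preserved),
  metrics averaged over folds and confusion counts pooled; every class needs
  at least k members.
- **Label polarity.** UCI-layout outcomes are mapped to the strings
  "healthy" (num = 0) and "patient" (num ≥ 1) internally, avoiding the 0/1
  polarity ambiguity of the numeric encodings.

## Known limitations

- Membership functions are fixed; no tuning or learned partitions.
- The method is designed for two classes. The CF formula and inference
  support more, but pruning and evaluation assume binary labels.
- The swarm objective is training accuracy under the current weights; there
  is no explicit regularisation beyond the g prune, the don't-care bias and
  boosting's coverage pressure, so small noisy datasets can still yield
  rules that memorise noise.
- Weighted-accuracy fitness makes no attempt at multi-objective
  interpretability trade-offs; rule-set compactness emerges from the
  initialisation bias and early stopping, not from an explicit penalty.
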