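"""Rule-edit algebra and the discrete swarm search."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import fuzzyswarm.ram_pso as rp
from fuzzyswarm import fuzzy_core as fc
from fuzzyswarm.boosting import WeightedDataset
from fuzzyswarm.data_io import SyntheticSpec, generate_synthetic, planted_two_rule_spec

strings5 = st.text(alphabet=fc.ALPHABET, min_size=5, max_size=5)


def rule(s, consequent="y", cf=1.0):
    return fc.decode(s, consequent, cf)


class TestRamAlgebra:
    def test_apply_ram_worked_example(self):
        # (S5, ML4, L2, M3, DC) + RAM(3, S2) -> (S5, ML4, S2, M3, DC)
        before = rule("a8240")
        after = rp.apply_ram(before, rp.RAMOp(3, fc.SYMBOLS["1"]))
        assert after.encode() == "a8140"
        assert before.encode() == "a8240"  # value semantics: input untouched

    def test_apply_ram_identity_and_override(self):
        r = rule("a8240")
        assert rp.apply_ram(r, rp.RAMOp(1, fc.SYMBOLS["a"])) == r
        seq = rp.RAMSequence((rp.RAMOp(2, fc.SYMBOLS["1"]), rp.RAMOp(2, fc.SYMBOLS["e"])))
        assert rp.apply_rams(r, seq).encode()[1] == "e"  # last op at a position wins

    def test_apply_ram_position_errors(self):
        with pytest.raises(IndexError):
            rp.apply_ram(rule("a8240"), rp.RAMOp(6, fc.SYMBOLS["1"]))
        with pytest.raises(IndexError):
            rp.RAMOp(0, fc.SYMBOLS["1"])

    def test_empty_sequence_is_identity(self):
        r = rule("0150b")
        assert rp.apply_rams(r, rp.RAMSequence()) == r

    def test_brams_worked_example(self):
        seq = rp.brams(rule("a8240"), rule("a8140"))
        assert len(seq) == 1
        (op,) = seq.ops
        assert op.position == 3 and op.new_symbol.code == "1"
        assert rp.brams(rule("a8240"), rule("a8240")) == rp.RAMSequence()

    def test_brams_length_mismatch(self):
        with pytest.raises(ValueError):
            rp.brams(rule("00"), rule("000"))

    @given(a=strings5, b=strings5)
    def test_brams_round_trip_and_hamming_length(self, a, b):
        ra, rb = rule(a), rule(b)
        seq = rp.brams(ra, rb)
        assert rp.apply_rams(ra, seq) == rb
        assert len(seq) == sum(x != y for x, y in zip(a, b))
        assert seq.is_basic

    @given(s=strings5, a=strings5, b=strings5, c=strings5)
    def test_merge_is_composition(self, s, a, b, c):
        """merge(A, B) acts on any rule exactly as A then B (the defining
        equivalence), and merging is associative up to that action."""
        r0 = rule(s)
        A, B, C = (rp.brams(rule(a), rule(b)), rp.brams(rule(b), rule(c)), rp.brams(rule(c), rule(a)))
        assert rp.apply_rams(r0, rp.merge(A, B)) == rp.apply_rams(rp.apply_rams(r0, A), B)
        left = rp.merge(rp.merge(A, B), C)
        right = rp.merge(A, rp.merge(B, C))
        assert rp.apply_rams(r0, left) == rp.apply_rams(r0, right)

    def test_merge_examples(self):
        s = rp.RAMSequence((rp.RAMOp(2, fc.SYMBOLS["3"]), rp.RAMOp(2, fc.SYMBOLS["4"])))
        assert rp.merge(rp.RAMSequence(), s).ops == s.to_basic().ops
        a = rp.RAMSequence((rp.RAMOp(2, fc.SYMBOLS["1"]),))
        b = rp.RAMSequence((rp.RAMOp(2, fc.SYMBOLS["2"]),))
        merged = rp.merge(a, b)
        assert merged.ops == (rp.RAMOp(2, fc.SYMBOLS["2"]),)

    def test_basic_form_idempotent(self):
        s = rp.RAMSequence(
            (rp.RAMOp(1, fc.SYMBOLS["1"]), rp.RAMOp(2, fc.SYMBOLS["2"]), rp.RAMOp(1, fc.SYMBOLS["3"]))
        )
        basic = s.to_basic()
        assert basic.is_basic
        assert basic.to_basic() == basic
        assert rp.apply_rams(rule("00000"), s) == rp.apply_rams(rule("00000"), basic)


class TestScaleRams:
    def test_endpoints(self, rng):
        seq = rp.brams(rule("00000"), rule("12345"))
        assert rp.scale_rams(0.0, seq, rng) == rp.RAMSequence()
        assert rp.scale_rams(1.0, seq, rng) == seq

    def test_out_of_range_clamped_with_warning(self, rng):
        seq = rp.brams(rule("00000"), rule("12345"))
        with pytest.warns(UserWarning):
            assert rp.scale_rams(1.5, seq, rng) == seq

    def test_expected_retention(self, rng):
        seq = rp.brams(rule("00000"), rule("eeeee"))  # 5 ops
        c, trials = 0.3, 4000
        lengths = [len(rp.scale_rams(c, seq, rng)) for _ in range(trials)]
        mean = np.mean(lengths)
        se = np.sqrt(5 * c * (1 - c) / trials)
        assert abs(mean - 5 * c) < 3 * se

    def test_zero_coefficients_leave_swarm_stationary(self, rng):
        """With inertia and both attraction coefficients at 0, the merged
        velocity is empty and applying it is the identity."""
        v = [(0, 3), (2, 7)]
        merged = rp._merge_ops(
            rp._scale_ops(0.0, v, rng),
            rp._scale_ops(0.0, [(1, 4)], rng),
            rp._scale_ops(0.0, [(3, 9)], rng),
        )
        assert merged == []
        codes = np.array([1, 2, 3, 4, 5])
        rp._apply_ops(codes, merged)
        assert (codes == [1, 2, 3, 4, 5]).all()


def _covered_toy():
    # rule "1" (S2, mu = 1 - x) with consequent A; three fully covered instances
    data = WeightedDataset(
        X=np.array([[0.0], [0.0], [0.0]]),
        labels=np.array(["A", "A", "B"], dtype=object),
    )
    return rule("1", "A"), data


class TestGScore:
    def test_hand_sum(self):
        r, data = _covered_toy()
        assert rp.g_score(r, data) == pytest.approx(0.5)  # NMP=1, NCP=2

    def test_clean_rule_is_zero(self):
        # the class-B instance at x=1 has mu=0: uncovered, so NMP=0
        r = rule("1", "A")
        clean = WeightedDataset(X=np.array([[0.0], [1.0]]), labels=np.array(["A", "B"], dtype=object))
        assert rp.g_score(r, clean) == 0.0

    def test_no_correct_coverage_is_infinite(self):
        r = rule("1", "A")
        data = WeightedDataset(X=np.array([[0.2]]), labels=np.array(["B"], dtype=object))
        assert rp.g_score(r, data) == np.inf

    def test_balanced_coverage_is_one(self):
        r = rule("1", "A")
        data = WeightedDataset(X=np.array([[0.0], [0.0]]), labels=np.array(["A", "B"], dtype=object))
        assert rp.g_score(r, data) == 1.0


class TestParticleFitness:
    def test_perfect_rules(self):
        data = WeightedDataset(
            X=np.array([[0.0], [1.0], [0.1], [0.9]]),
            labels=np.array(["A", "B", "A", "B"], dtype=object),
        )
        rules = [rule("1", "A", 1.0), rule("2", "B", 1.0)]
        assert rp.particle_fitness(rules, data) == 1.0

    def test_empty_rule_set(self):
        data = WeightedDataset(X=np.array([[0.5]]), labels=np.array(["A"], dtype=object))
        assert rp.particle_fitness([], data) == 0.0

    def test_half_weight_covered(self):
        # one perfect rule for class A; class B instances stay unclassified
        data = WeightedDataset(
            X=np.array([[0.0], [0.0], [1.0], [1.0]]),
            labels=np.array(["A", "A", "B", "B"], dtype=object),
        )
        assert rp.particle_fitness([rule("1", "A", 1.0)], data) == pytest.approx(0.5)

    def test_zero_total_weight_rejected(self):
        data = WeightedDataset(
            X=np.array([[0.0]]), labels=np.array(["A"], dtype=object), weights=np.array([0.0])
        )
        with pytest.raises(rp.DegenerateDataError):
            rp.particle_fitness([rule("1", "A", 1.0)], data)


class TestPsoRun:
    def _dataset(self, seed=0, noise=0.0):
        spec = SyntheticSpec(
            n_attributes=5,
            n_instances=200,
            rules=[rule("10000", "pos"), rule("20000", "neg")],
            noise_rate=noise,
            fallback_class="neg",
        )
        inst, _ = generate_synthetic(spec, np.random.default_rng(seed))
        return WeightedDataset.from_instances(inst)

    def test_deterministic_under_fixed_seed(self):
        data = self._dataset()
        r1 = rp.pso_run(data, rp.SwarmConfig(), np.random.default_rng(42))
        r2 = rp.pso_run(data, rp.SwarmConfig(), np.random.default_rng(42))
        assert [(r.encode(), r.consequent, r.cf) for r in r1] == [
            (r.encode(), r.consequent, r.cf) for r in r2
        ]

    def test_rule_count_bounded_by_B(self):
        data = self._dataset()
        cfg = rp.SwarmConfig(n_rules=6)
        rules = rp.pso_run(data, cfg, np.random.default_rng(0))
        assert len(rules) <= 6
        assert all(r.cf > 0 for r in rules)

    def test_single_class_data_rejected(self):
        data = WeightedDataset(X=np.array([[0.1], [0.2]]), labels=np.array(["A", "A"], dtype=object))
        with pytest.raises(rp.DegenerateDataError):
            rp.pso_run(data, rp.SwarmConfig(), np.random.default_rng(0))

    def test_separable_data_recovery(self):
        """On noise-free data separable by one 1-antecedent rule per class the
        swarm reaches >= 0.9 weighted accuracy in >= 8 of 10 seeds, and some
        seed separates perfectly."""
        fits = []
        for seed in range(10):
            data = self._dataset(seed=seed)
            rules = rp.pso_run(data, rp.SwarmConfig(), np.random.default_rng(seed))
            fits.append(rp.particle_fitness(rules, data))
        assert sum(f >= 0.9 for f in fits) >= 8
        assert max(fits) == 1.0

    def test_planted_rule_recovery_with_noise(self):
        """Two disjoint planted rules, 5% label noise: a single swarm run
        reaches >= 0.9 training accuracy in >= 8 of 10 seeds."""
        spec = planted_two_rule_spec()
        ok = 0
        for seed in range(10):
            g = np.random.default_rng(seed)
            inst, _ = generate_synthetic(spec, g)
            data = WeightedDataset.from_instances(inst)
            rules = rp.pso_run(data, rp.SwarmConfig(), g)
            ok += rp.particle_fitness(rules, data) >= 0.9
        assert ok >= 8


def test_swarm_config_validation():
    with pytest.raises(ValueError):
        rp.SwarmConfig(swarm_size=1)
    with pytest.raises(ValueError):
        rp.SwarmConfig(n_rules=0)
    with pytest.raises(ValueError):
        rp.SwarmConfig(stall_limit=0)
    cfg = rp.SwarmConfig.from_dict({"swarm_size": 10, "n_rules": 5, "ignored": 1} | {})
    assert cfg.swarm_size == 10 and cfg.n_rules == 5
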