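import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from comorbidarm.arm import (
    MiningConfig,
    Rule,
    TransactionSet,
    confidence,
    lift,
    mine_rules,
    support,
)

from oracles import brute_rules, brute_support, random_transactions


@pytest.fixture()
def small_ts():
    rng = np.random.default_rng(12)
    return TransactionSet(random_transactions(rng, 6, 60))


class TestSupport:
    def test_empty_itemset_is_one(self, small_ts):
        assert support(set(), small_ts) == 1.0

    def test_absent_itemset_is_zero(self, small_ts):
        ts = TransactionSet(small_ts.transactions, universe=list(small_ts.universe) + ["zz"])
        assert support({"zz"}, ts) == 0.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            tx = random_transactions(rng, 5, 40)
            ts = TransactionSet(tx)
            for _ in range(10):
                k = rng.integers(1, 4)
                itemset = set(rng.choice(ts.universe, size=k, replace=False))
                assert support(itemset, ts) == brute_support(itemset, tx)

    def test_anti_monotone(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            tx = random_transactions(rng, 6, 50)
            ts = TransactionSet(tx)
            items = list(ts.universe)
            sub = set(rng.choice(items, size=2, replace=False))
            sup = sub | set(rng.choice(items, size=2, replace=False))
            assert support(sub, ts) >= support(sup, ts)

    def test_empty_transaction_set_rejected(self):
        ts = TransactionSet([], universe=["a"])
        with pytest.raises(ValueError):
            ts.support({"a"})


class TestConfidenceAndLift:
    def test_confidence_consequent_subset_of_antecedent(self):
        ts = TransactionSet([{"a", "b"}, {"a", "b", "c"}, {"c"}])
        assert confidence({"a", "b"}, {"a"}, ts) == 1.0

    def test_confidence_undefined_for_zero_support_antecedent(self):
        ts = TransactionSet([{"a"}], universe=["a", "b"])
        with pytest.raises(ValueError, match="zero support"):
            confidence({"b"}, {"a"}, ts)

    def test_lift_exactly_one_under_constructed_independence(self):
        # 20 transactions; P(a)=0.5, P(b)=0.4, P(ab)=0.2 factorises exactly
        tx = (
            [{"a", "b"}] * 4 + [{"a"}] * 6 + [{"b"}] * 4 + [set()] * 6
        )
        ts = TransactionSet(tx, universe=["a", "b"])
        assert lift({"a"}, {"b"}, ts) == 1.0

    def test_lift_symmetry_and_brute_force(self):
        rng = np.random.default_rng(21)
        for _ in range(30):
            tx = random_transactions(rng, 6, 50)
            ts = TransactionSet(tx)
            present = [i for i in ts.universe if ts.count({i})]
            if len(present) < 2:
                continue
            x, y = rng.choice(present, size=2, replace=False)
            lf = lift({x}, {y}, ts)
            assert lf == pytest.approx(lift({y}, {x}, ts), rel=1e-12)
            pxy = brute_support({x, y}, tx)
            px, py = brute_support({x}, tx), brute_support({y}, tx)
            assert lf == pytest.approx(pxy / (px * py), rel=1e-12)
            assert (lf > 1) == (pxy > px * py)

    def test_lift_undefined_for_zero_support_consequent(self):
        ts = TransactionSet([{"a"}], universe=["a", "b"])
        with pytest.raises(ValueError, match="zero support"):
            lift({"a"}, {"b"}, ts)


ITEMS = ["a", "b", "c", "d", "e"]
transactions_strategy = st.lists(
    st.frozensets(st.sampled_from(ITEMS)), min_size=1, max_size=40
)


@settings(max_examples=60, derandomize=True)
@given(tx=transactions_strategy)
def test_rule_metric_laws_hold_on_arbitrary_transactions(tx):
    """For every emitted rule: s <= c, metrics lie in range, support is
    anti-monotone, and lift > 1 iff joint support beats the marginal
    product."""
    ts = TransactionSet(tx, universe=ITEMS)
    cfg = MiningConfig(consequent_sizes=frozenset({1, 2, 3}), max_rule_size=4,
                       k=10**6, min_lift=0.0)
    for r in mine_rules(ts, cfg):
        assert 0 <= r.support <= r.confidence <= 1
        assert r.lift > 0
        assert support(r.antecedent | r.consequent, ts) <= min(
            support(r.antecedent, ts), support(r.consequent, ts)
        )
        joint = support(r.antecedent | r.consequent, ts)
        prod = support(r.antecedent, ts) * support(r.consequent, ts)
        if r.lift > 1:
            assert joint > prod
        elif r.lift < 1:
            assert joint < prod
        else:
            assert joint == pytest.approx(prod)


class TestRule:
    def test_overlapping_sets_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            Rule(frozenset({"a"}), frozenset({"a", "b"}), 0.1, 0.5, 2.0)

    def test_relations_and_label(self):
        r = Rule(frozenset({"BPD"}), frozenset({"b", "a"}), 0.1, 0.5, 2.0)
        assert r.relations == 3
        assert r.label == "BPD => a & b"


class TestMineRules:
    CFG = MiningConfig(consequent_sizes=frozenset({1, 2, 3}), max_rule_size=4, k=10**6)

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(77)
        for _ in range(15):
            tx = random_transactions(rng, int(rng.integers(3, 7)), int(rng.integers(10, 80)))
            ts = TransactionSet(tx)
            got = mine_rules(ts, self.CFG)
            want = brute_rules(tx, consequent_sizes=(1, 2, 3), max_rule_size=4)
            assert [(r.antecedent, r.consequent) for r in got] == [
                (x, y) for x, y, *_ in want
            ]
            for r, (_, _, s, c, lf) in zip(got, want):
                assert (r.support, r.confidence, r.lift) == pytest.approx((s, c, lf))

    def test_identical_transactions_yield_no_rules(self):
        ts = TransactionSet([{"a", "b", "c"}] * 10)
        assert mine_rules(ts, self.CFG) == []

    def test_k_truncation_keeps_top_lift(self, small_ts):
        full = mine_rules(small_ts, self.CFG)
        if not full:
            pytest.skip("degenerate sample")
        top1 = mine_rules(small_ts, MiningConfig(
            consequent_sizes=frozenset({1, 2, 3}), max_rule_size=4, k=1))
        assert top1 == full[:1]

    def test_sorted_by_lift_descending(self, small_ts):
        rules = mine_rules(small_ts, self.CFG)
        lifts = [r.lift for r in rules]
        assert lifts == sorted(lifts, reverse=True)

    def test_antecedent_constraint(self):
        rng = np.random.default_rng(5)
        tx = random_transactions(rng, 6, 80)
        tx = [t | {"IDX"} if rng.random() < 0.3 else t for t in tx]
        ts = TransactionSet(tx)
        cfg = MiningConfig(
            antecedent_constraint=frozenset({"IDX"}),
            consequent_sizes=frozenset({2, 3}),
            max_rule_size=4,
            k=10**6,
        )
        got = mine_rules(ts, cfg)
        assert got  # positive co-occurrence by construction is likely
        assert all(r.antecedent == frozenset({"IDX"}) for r in got)
        assert all(len(r.consequent) in (2, 3) for r in got)
        want = brute_rules(tx, consequent_sizes=(2, 3), max_rule_size=4,
                           antecedent_constraint={"IDX"})
        assert [(r.antecedent, r.consequent) for r in got] == [
            (x, y) for x, y, *_ in want
        ]

    def test_tie_break_is_input_order_invariant(self):
        rng = np.random.default_rng(8)
        tx = random_transactions(rng, 5, 40)
        a = mine_rules(TransactionSet(tx), self.CFG)
        b = mine_rules(TransactionSet(tx[::-1]), self.CFG)
        assert a == b

    def test_universe_budget_error(self):
        ts = TransactionSet([], universe=[f"i{j}" for j in range(30)])
        ts.masks = np.array([0], dtype=np.uint64)
        ts.n = 1
        cfg = MiningConfig(itemset_budget=100)
        with pytest.raises(ValueError, match="budget"):
            mine_rules(ts, cfg)

    def test_empty_transactions_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            mine_rules(TransactionSet([], universe=["a"]), self.CFG)

    def test_strict_min_lift(self):
        # a and b perfectly correlated -> lift 2 passes; independent pair fails
        tx = [{"a", "b"}] * 5 + [set()] * 5
        rules = mine_rules(TransactionSet(tx, universe=["a", "b"]),
                           MiningConfig(consequent_sizes=frozenset({1}), k=10))
        assert {(tuple(r.antecedent), tuple(r.consequent)) for r in rules} == {
            (("a",), ("b",)), (("b",), ("a",))
        }
        assert all(r.lift == 2.0 for r in rules)
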