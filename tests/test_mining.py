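"""Transaction encoding, Apriori vs exhaustive oracle, rule measures and ranking."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from comorbmine import (
    MiningParams,
    PrincipalSubgroup,
    TransactionSet,
    apriori,
    brute_force_frequent,
    build_cohort,
    confidence,
    encode_transactions,
    generate_rules,
    is_scale,
    lift,
    mine_subgroup,
    rank_rules,
    rules_to_frame,
    support,
)
from comorbmine.mining import AssociationRule, Itemset

from conftest import make_record, make_stratum


def ts_from_lists(lists, n=None, universe=None):
    transactions = tuple(frozenset(t) for t in lists)
    items = sorted(set().union(*transactions)) if transactions else []
    return TransactionSet(
        n=n if n is not None else len(lists),
        universe=tuple(universe) if universe else tuple(items),
        transactions=transactions,
    )


TOY = ts_from_lists([{"A", "B"}, {"A", "B"}, {"A", "C"}, {"B"}, set()])


class TestMeasures:
    def test_support_reference_values(self):
        assert round(support(152, 1361), 3) == 0.112
        assert round(support(74, 4539), 3) == 0.016
        assert support(0, 1000) == 0.0

    def test_support_validates(self):
        with pytest.raises(ValueError):
            support(1, 0)
        with pytest.raises(ValueError):
            support(5, 4)

    def test_confidence_is_joint_over_antecedent(self):
        assert confidence(152, 266) == pytest.approx(152 / 266)
        assert confidence(7, 7) == 1.0
        with pytest.raises(ValueError):
            confidence(1, 0)

    def test_reverse_confidence_reconstruction(self):
        # P(consequent) recovered from forward confidence / lift
        p_b = 0.639 / 1.994
        assert round((152 / 1361) / p_b, 3) == 0.349

    def test_lift_examples(self):
        assert lift(0.112, 0.1753, 0.3204) == pytest.approx(1.994, abs=5e-4)
        s = 0.2
        assert lift(s, s, s) == pytest.approx(1 / s)
        with pytest.raises(ValueError):
            lift(0.1, 0.0, 0.5)

    def test_is_scale_reference_values(self):
        assert round(is_scale(152 / 1361, 1.994), 3) == 0.472
        assert round(is_scale(4 / 305, 24.898), 3) == 0.571
        assert is_scale(1.0, 1.0) == 1.0

    def test_is_scale_is_cosine(self):
        # IS == P(AB)/sqrt(P(A)P(B)) for counts (joint, a, b, n)
        joint, a, b, n = 30, 60, 90, 500
        sup = support(joint, n)
        l = lift(sup, support(a, n), support(b, n))
        cosine = (joint / n) / math.sqrt((a / n) * (b / n))
        assert is_scale(sup, l) == pytest.approx(cosine, rel=1e-12)


class TestEncodeTransactions:
    def test_blocks_deduplicated_and_empty_retained(self, block_table):
        records = [
            make_record("F03", ["I10", "I13"], patient_id="a"),
            make_record("F03", [], patient_id="b"),
        ]
        ts = encode_transactions(build_cohort(records, block_table), PrincipalSubgroup.DEMENTIA)
        assert ts.n == 2
        assert ts.transactions[0] == frozenset({"I10-I15"})
        assert ts.transactions[1] == frozenset()

    def test_principal_excluded_but_same_chapter_items_kept(self, block_table):
        # principal F03 with additional F00: the dementia block is still an item
        records = [make_record("F03", ["F00"], patient_id="a")]
        ts = encode_transactions(build_cohort(records, block_table), PrincipalSubgroup.DEMENTIA)
        assert ts.transactions[0] == frozenset({"F00-F03"})

    def test_unmapped_codes_dropped_and_counted(self, block_table):
        records = [make_record("F03", ["U50", "I10"], patient_id="a")]
        ts = encode_transactions(build_cohort(records, block_table), PrincipalSubgroup.DEMENTIA)
        assert ts.transactions[0] == frozenset({"I10-I15"})
        assert ts.n_unmapped_codes == 1

    def test_empty_stratum_raises_with_subgroup_name(self, block_table):
        cohort = build_cohort([make_record("F03", [])], block_table)
        with pytest.raises(ValueError, match="F30-F39"):
            encode_transactions(cohort, PrincipalSubgroup.MOOD)

    def test_stratum_size_from_reconstructed_cohort(self, dementia_cohort):
        ts = encode_transactions(dementia_cohort, PrincipalSubgroup.DEMENTIA)
        assert ts.n == 1361


class TestApriori:
    def test_toy_example(self):
        result = {tuple(sorted(s.items)): s.count for s in apriori(TOY, 0.4, max_size=3)}
        assert result == {("A",): 3, ("B",): 3, ("A", "B"): 2}

    def test_min_support_above_one_yields_nothing(self):
        assert apriori(TOY, 1.01) == []

    def test_downward_closure(self):
        rng = np.random.default_rng(7)
        ts = random_transaction_set(rng, n_items=10, n_trans=80)
        frequent = {s.items: s.count for s in apriori(ts, 0.05, max_size=4)}
        for items, count in frequent.items():
            for k in range(1, len(items)):
                for sub in itertools.combinations(items, k):
                    assert frozenset(sub) in frequent
                    assert frequent[frozenset(sub)] >= count

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(40):
            ts = random_transaction_set(rng)
            min_sup = float(rng.uniform(0.0, 0.5))
            got = {s.items: s.count for s in apriori(ts, min_sup, max_size=len(ts.universe) or 1)}
            want = {s.items: s.count for s in brute_force_frequent(ts, min_sup)}
            assert got == want

    def test_empty_transactions_only(self):
        ts = ts_from_lists([set(), set(), set()], universe=["A"])
        assert apriori(ts, 0.0) == []
        assert brute_force_frequent(ts, 0.0) == []

    def test_brute_force_rejects_large_universe(self):
        ts = ts_from_lists([set()], universe=[f"i{k}" for k in range(21)])
        with pytest.raises(ValueError, match="too large"):
            brute_force_frequent(ts, 0.1)


def random_transaction_set(rng, n_items=None, n_trans=None) -> TransactionSet:
    n_items = n_items or int(rng.integers(1, 13))
    n_trans = n_trans or int(rng.integers(1, 60))
    items = [f"B{k:02d}" for k in range(n_items)]
    density = rng.uniform(0.05, 0.5)
    lists = [
        {it for it in items if rng.random() < density} for _ in range(n_trans)
    ]
    return ts_from_lists(lists, n=n_trans, universe=items)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1), st.floats(min_value=0.0, max_value=0.8))
def test_apriori_equals_brute_force_property(seed, min_sup):
    """Levelwise search and exhaustive enumeration agree on arbitrary instances."""
    rng = np.random.default_rng(seed)
    ts = random_transaction_set(rng)
    got = sorted((tuple(sorted(s.items)), s.count) for s in apriori(ts, min_sup, max_size=len(ts.universe)))
    want = sorted((tuple(sorted(s.items)), s.count) for s in brute_force_frequent(ts, min_sup))
    assert got == want


class TestRules:
    def test_toy_rule_emission(self):
        frequent = apriori(TOY, 0.2, max_size=2)
        params = MiningParams(min_support=0.2, min_confidence=0.5, min_lift=1.0)
        rules = {r.label: m for r, m in generate_rules(frequent, TOY, params)}
        assert "A -> B" in rules
        m = rules["A -> B"]
        assert m.support == pytest.approx(0.4)
        assert m.confidence == pytest.approx(2 / 3)
        assert m.lift == pytest.approx(0.4 / (0.6 * 0.6))

    def test_lift_exactly_one_not_emitted(self):
        # A and B independent by construction: P(AB)=0.25=P(A)P(B)
        ts = ts_from_lists([{"A", "B"}, {"A"}, {"B"}, set()])
        frequent = apriori(ts, 0.25, max_size=2)
        rules = generate_rules(frequent, ts, MiningParams(min_support=0.0, min_confidence=0.0))
        assert rules == []

    def test_violated_closure_raises(self):
        ts = TOY
        bad = [Itemset(frozenset({"A", "B"}), 2), Itemset(frozenset({"A"}), 3)]
        with pytest.raises(ValueError, match="closed downward"):
            generate_rules(bad, ts, MiningParams(min_support=0.0, min_confidence=0.0))

    def test_bidirectional_pair_shares_lift_and_is(self, dementia_cohort):
        ranked = mine_subgroup(dementia_cohort, PrincipalSubgroup.DEMENTIA)
        by_label = {r.label: m for r, m in ranked}
        for a, b in [("E10-E14", "I10-I15"), ("F00-F03", "G30-G32"), ("I10-I15", "I60-I69")]:
            fwd, rev = by_label[f"{a} -> {b}"], by_label[f"{b} -> {a}"]
            assert fwd.lift == pytest.approx(rev.lift, rel=1e-12)
            assert fwd.is_scale == pytest.approx(rev.is_scale, rel=1e-12)

    def test_metric_identities_over_all_mined_rules(self, dementia_cohort):
        ranked = mine_subgroup(dementia_cohort, PrincipalSubgroup.DEMENTIA)
        assert ranked, "expected rules from the reconstructed stratum"
        for _, m in ranked:
            assert m.is_scale**2 == pytest.approx(m.support * m.lift, rel=1e-12)
            assert m.confidence >= m.support - 1e-12
            assert m.support <= m.confidence <= 1.0 + 1e-12

    def test_rank_order_and_tie_breaks(self):
        def entry(label_items, cons, sup, l):
            rule = AssociationRule(frozenset(label_items), cons, 1)
            from comorbmine.mining import RuleMetrics

            return rule, RuleMetrics(sup, 0.5, l, math.sqrt(sup * l))

        rules = [
            entry({"B"}, "C", 0.1, 4.0),
            entry({"A"}, "C", 0.1, 4.0),   # IS tie, support tie -> alphabetical
            entry({"A"}, "B", 0.4, 4.0),   # highest IS first
        ]
        ranked = rank_rules(rules)
        assert [r.label for r, _ in ranked] == ["A -> B", "A -> C", "B -> C"]

    def test_single_rule_ranks_to_itself(self):
        from comorbmine.mining import RuleMetrics

        only = (AssociationRule(frozenset({"A"}), "B", 1), RuleMetrics(0.1, 0.5, 2.0, 0.447))
        assert rank_rules([only]) == [only]


class TestMineSubgroup:
    def test_reconstructed_dementia_table(self, dementia_cohort):
        """The reconstructed stratum reproduces the reference ranked rule table."""
        frame = rules_to_frame(
            mine_subgroup(dementia_cohort, PrincipalSubgroup.DEMENTIA), "F00-F03"
        )
        assert len(frame) == 6
        assert list(frame["is_scale"]) == [0.472, 0.472, 0.431, 0.431, 0.346, 0.346]
        top = frame.iloc[0]
        assert {top["antecedent"], top["consequent"]} == {"E10-E14", "I10-I15"}
        assert top["support"] == 0.112
        fwd = frame[(frame["antecedent"] == "E10-E14") & (frame["consequent"] == "I10-I15")].iloc[0]
        assert (fwd["confidence"], fwd["lift"]) == (0.639, 1.994)
        rev = frame[(frame["antecedent"] == "I10-I15") & (frame["consequent"] == "E10-E14")].iloc[0]
        assert rev["confidence"] == 0.349

    def test_min_support_on_small_stratum(self, block_table):
        # min_support 0.01 on a stratum of 100 means a single joint patient qualifies
        groups = [(1, ["E10", "I10"]), (30, ["E10"]), (30, ["I10"])]
        cohort = build_cohort(make_stratum("F20", 100, groups), block_table)
        ts = encode_transactions(cohort, PrincipalSubgroup.SCHIZOPHRENIA)
        frequent = {tuple(sorted(s.items)): s.count for s in apriori(ts, 0.01)}
        assert frequent[("E10-E14", "I10-I15")] == 1

    def test_planted_pair_dominates(self, block_table):
        # strong pair E/I over background noise blocks
        groups = [
            (60, ["E10", "I10"]),
            (20, ["E10"]),
            (20, ["I10"]),
            (100, ["K20"]),
            (5, ["K20", "K70"]),
            (95, ["K70"]),
        ]
        cohort = build_cohort(make_stratum("F20", 1000, groups), block_table)
        ranked = mine_subgroup(cohort, PrincipalSubgroup.SCHIZOPHRENIA)
        top_pair = {ranked[0][0].label, ranked[1][0].label}
        assert top_pair == {"E10-E14 -> I10-I15", "I10-I15 -> E10-E14"}
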