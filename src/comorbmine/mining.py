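"""Transaction encoding, from-scratch Apriori, rule induction, and IS-scale ranking.

Each patient in a principal-diagnosis stratum becomes one transaction: the set
of distinct intermediate blocks covering their additional diagnoses. Patients
without comorbidities contribute empty transactions that still count in the
support denominator — support is always a fraction of the whole stratum.

Rules are scored with four measures:

* support(A→B)    = P(A ∪ B), the joint fraction of patients,
* confidence(A→B) = P(A ∪ B) / P(A),
* lift(A→B)       = P(A ∪ B) / (P(A)·P(B)),
* IS scale        = sqrt(support × lift) = P(A ∪ B)/sqrt(P(A)·P(B)),

the last being the cosine interest-support measure used as the ranking key:
it discounts rules that owe a large lift to a tiny support, or vice versa.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from ._util import round_half_up
from .cohort import Cohort
from .icd import PrincipalSubgroup

__all__ = [
    "TransactionSet",
    "Itemset",
    "AssociationRule",
    "RuleMetrics",
    "MiningParams",
    "encode_transactions",
    "support",
    "confidence",
    "lift",
    "is_scale",
    "apriori",
    "brute_force_frequent",
    "generate_rules",
    "rank_rules",
    "mine_subgroup",
    "rules_to_frame",
]


@dataclass(frozen=True)
class TransactionSet:
    """Per-patient item sets over a block universe, for one stratum.

    ``n`` counts every patient in the stratum, including those whose item set
    is empty; it is the denominator of every support in the stratum.
    """

    n: int
    universe: tuple[str, ...]
    transactions: tuple[frozenset[str], ...]
    n_unmapped_codes: int = 0

    def __post_init__(self) -> None:
        if self.n < len([t for t in self.transactions if t]):
            raise ValueError("n smaller than the number of non-empty transactions")
        allowed = set(self.universe)
        for t in self.transactions:
            if not t <= allowed:
                raise ValueError(f"transaction items {sorted(t - allowed)} not in universe")


@dataclass(frozen=True)
class Itemset:
    """A non-empty set of block identifiers with its exact patient count."""

    items: frozenset[str]
    count: int


@dataclass(frozen=True)
class AssociationRule:
    """antecedent → consequent with the joint patient count."""

    antecedent: frozenset[str]
    consequent: str
    joint_count: int

    def __post_init__(self) -> None:
        if not self.antecedent:
            raise ValueError("antecedent must be non-empty")
        if self.consequent in self.antecedent:
            raise ValueError("consequent must not appear in the antecedent")

    @property
    def label(self) -> str:
        return f"{','.join(sorted(self.antecedent))} -> {self.consequent}"


@dataclass(frozen=True)
class RuleMetrics:
    support: float
    confidence: float
    lift: float
    is_scale: float


@dataclass(frozen=True)
class MiningParams:
    """Selection thresholds: support and confidence are inclusive lower bounds,
    the lift filter is strict (> min_lift)."""

    min_support: float = 0.01
    min_confidence: float = 0.1
    min_lift: float = 1.0
    max_itemset_size: int = 3

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_support <= 1.0:
            raise ValueError("min_support must be in [0, 1]")
        if not 0.0 <= self.min_confidence <= 1.0:
            raise ValueError("min_confidence must be in [0, 1]")
        if self.min_lift < 0:
            raise ValueError("min_lift must be >= 0")
        if self.max_itemset_size < 2:
            raise ValueError("max_itemset_size must be >= 2")


# --- measures ----------------------------------------------------------------

def support(joint_count: int, n: int) -> float:
    """Joint count over the full stratum size."""
    if n <= 0:
        raise ValueError("stratum size n must be positive")
    if not 0 <= joint_count <= n:
        raise ValueError("joint_count must lie in [0, n]")
    return joint_count / n

def confidence(joint_count: int, antecedent_count: int) -> float:
    """Joint count over the antecedent count."""
    if antecedent_count <= 0:
        raise ValueError("antecedent_count must be positive")
    if not 0 <= joint_count <= antecedent_count:
        raise ValueError("joint_count must lie in [0, antecedent_count]")
    return joint_count / antecedent_count

def lift(support_joint: float, support_a: float, support_b: float) -> float:
    """Joint support over the product of the marginal supports."""
    if support_a <= 0 or support_b <= 0:
        raise ValueError("marginal supports must be positive")
    return support_joint / (support_a * support_b)

def is_scale(support_value: float, lift_value: float) -> float:
    """sqrt(support × lift), the cosine measure P(AB)/sqrt(P(A)P(B))."""
    if support_value < 0 or lift_value < 0:
        raise ValueError("support and lift must be non-negative")
    return math.sqrt(support_value * lift_value)


# --- transaction encoding ----------------------------------------------------

def encode_transactions(cohort: Cohort, subgroup: PrincipalSubgroup) -> TransactionSet:
    """One transaction per stratum patient: distinct blocks of their additional codes.

    Additional codes that fall outside every block of the table are dropped
    from the transaction but tallied in ``n_unmapped_codes``. Patients with no
    comorbidity contribute empty transactions and still count in ``n``.
    """
    members = cohort.stratum(subgroup)
    if not members:
        raise ValueError(f"stratum {subgroup.label} is empty")
    table = cohort.block_table
    unmapped = 0
    transactions = []
    seen_items: set[str] = set()
    for rec in members:
        items = set()
        for code in rec.additional_dx:
            blk = table.assign(code)
            if blk is None:
                unmapped += 1
            else:
                items.add(blk.id)
        seen_items.update(items)
        transactions.append(frozenset(items))
    universe = tuple(b.id for b in table if b.id in seen_items)
    return TransactionSet(
        n=len(members),
        universe=universe,
        transactions=tuple(transactions),
        n_unmapped_codes=unmapped,
    )


# --- frequent itemsets -------------------------------------------------------

def apriori(ts: TransactionSet, min_support: float = 0.01, max_size: int = 3) -> list[Itemset]:
    """Level-wise frequent-itemset search with prefix-join candidate generation.

    Returns exactly the itemsets of size <= ``max_size`` whose count satisfies
    both count/n >= ``min_support`` and count >= 1, with exact counts. Size-k
    candidates are joined from frequent (k−1)-sets sharing a (k−2)-prefix and
    pruned when any (k−1)-subset is infrequent (downward closure).
    """
    n = ts.n
    threshold = max(1, math.ceil(min_support * n))

    counts1: dict[str, int] = {}
    for t in ts.transactions:
        for item in t:
            counts1[item] = counts1.get(item, 0) + 1
    frequent: dict[frozenset[str], int] = {
        frozenset([item]): c for item, c in counts1.items() if c >= threshold
    }
    result = dict(frequent)

    level_sets = sorted((item,) for item, c in counts1.items() if c >= threshold)
    k = 2
    while level_sets and k <= max_size:
        candidates = _join_candidates(level_sets, result)
        if not candidates:
            break
        counts = _count_candidates(ts.transactions, candidates, k)
        level_sets = sorted(c for c in candidates if counts.get(c, 0) >= threshold)
        for c in level_sets:
            result[frozenset(c)] = counts[c]
        k += 1

    return [Itemset(items, cnt) for items, cnt in result.items()]


def _join_candidates(
    level_sets: Sequence[tuple[str, ...]],
    frequent: dict[frozenset[str], int],
) -> set[tuple[str, ...]]:
    """Prefix-join of sorted (k−1)-tuples, with downward-closure pruning."""
    candidates = set()
    level_sets = sorted(level_sets)
    for i, a in enumerate(level_sets):
        for b in level_sets[i + 1 :]:
            if a[:-1] != b[:-1]:
                break  # sorted order: no further tuple shares the prefix
            cand = a + (b[-1],)
            if all(
                frozenset(cand[:j] + cand[j + 1 :]) in frequent
                for j in range(len(cand))
            ):
                candidates.add(cand)
    return candidates


def _count_candidates(
    transactions: Sequence[frozenset[str]],
    candidates: set[tuple[str, ...]],
    k: int,
) -> dict[tuple[str, ...], int]:
    """Count candidates by enumerating the size-k subsets occurring in each
    transaction — cheap because comorbidity transactions are short."""
    counts: dict[tuple[str, ...], int] = {}
    for t in transactions:
        if len(t) < k:
            continue
        for combo in itertools.combinations(sorted(t), k):
            if combo in candidates:
                counts[combo] = counts.get(combo, 0) + 1
    return counts


def brute_force_frequent(ts: TransactionSet, min_support: float) -> list[Itemset]:
    """Exhaustive enumeration over every non-empty subset of the universe.

    Independent oracle for :func:`apriori`; refuses universes above 20 items.
    Frequent means count/n >= min_support and count >= 1, any size.
    """
    if len(ts.universe) > 20:
        raise ValueError(f"universe of {len(ts.universe)} items is too large to enumerate")
    n = ts.n
    threshold = max(1, math.ceil(min_support * n))
    out = []
    items = sorted(ts.universe)
    for size in range(1, len(items) + 1):
        for combo in itertools.combinations(items, size):
            s = frozenset(combo)
            count = sum(1 for t in ts.transactions if s <= t)
            if count >= threshold:
                out.append(Itemset(s, count))
    return out


# --- rules -------------------------------------------------------------------

def generate_rules(
    frequent: Iterable[Itemset],
    ts: TransactionSet,
    params: MiningParams = MiningParams(),
) -> list[tuple[AssociationRule, RuleMetrics]]:
    """Induce single-consequent rules from frequent itemsets of size >= 2.

    For each such itemset and each choice of one item as consequent, the rule
    is emitted iff support >= min_support, confidence >= min_confidence and
    lift > min_lift (strict). All metrics come from exact counts; a frequent
    set whose subset counts are missing (violated downward closure) raises.
    """
    counts = {fs.items: fs.count for fs in frequent}
    n = ts.n
    out = []
    for items, joint in counts.items():
        if len(items) < 2:
            continue
        for consequent in sorted(items):
            antecedent = items - {consequent}
            ant_count = counts.get(antecedent)
            cons_count = counts.get(frozenset([consequent]))
            if ant_count is None or cons_count is None:
                raise ValueError(
                    f"missing subset count for itemset {sorted(items)}: "
                    "frequent collection is not closed downward"
                )
            sup = support(joint, n)
            conf = confidence(joint, ant_count)
            lft = lift(sup, support(ant_count, n), support(cons_count, n))
            if sup < params.min_support or conf < params.min_confidence:
                continue
            if not lft > params.min_lift:
                continue
            rule = AssociationRule(antecedent, consequent, joint)
            out.append((rule, RuleMetrics(sup, conf, lft, is_scale(sup, lft))))
    return out


def rank_rules(
    rules: Iterable[tuple[AssociationRule, RuleMetrics]]
) -> list[tuple[AssociationRule, RuleMetrics]]:
    """Sort descending by IS scale, then descending support, then rule label."""
    return sorted(rules, key=lambda rm: (-rm[1].is_scale, -rm[1].support, rm[0].label))


def mine_subgroup(
    cohort: Cohort,
    subgroup: PrincipalSubgroup,
    params: MiningParams = MiningParams(),
) -> list[tuple[AssociationRule, RuleMetrics]]:
    """encode → apriori → rule induction → IS ranking, for one stratum."""
    ts = encode_transactions(cohort, subgroup)
    frequent = apriori(ts, min_support=params.min_support, max_size=params.max_itemset_size)
    return rank_rules(generate_rules(frequent, ts, params))


def rules_to_frame(
    ranked: Sequence[tuple[AssociationRule, RuleMetrics]],
    stratum: str,
    ndigits: Optional[int] = 3,
) -> pd.DataFrame:
    """Ranked rule table as a DataFrame.

    Metrics are rounded half away from zero to ``ndigits`` decimals at this
    output boundary only; pass ``ndigits=None`` for full precision.
    """
    fmt = (lambda x: x) if ndigits is None else (lambda x: round_half_up(x, ndigits))
    rows = [
        {
            "stratum": stratum,
            "antecedent": ",".join(sorted(rule.antecedent)),
            "consequent": rule.consequent,
            "n_patients": rule.joint_count,
            "support": fmt(m.support),
            "confidence": fmt(m.confidence),
            "lift": fmt(m.lift),
            "is_scale": fmt(m.is_scale),
        }
        for rule, m in ranked
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "stratum",
            "antecedent",
            "consequent",
            "n_patients",
            "support",
            "confidence",
            "lift",
            "is_scale",
        ],
    )
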