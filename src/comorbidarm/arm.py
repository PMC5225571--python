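"""Association rule mining in the lift-only regime.

Support and confidence thresholds are conceptually zero; rules are required
to have lift strictly above 1 (positive association), ranked by lift
descending, and truncated to the top *k*.  Because zero-support mining is
exponential in the size of the item universe, level-wise enumeration is
bounded by a maximum rule size (antecedent plus consequent; default 4) and a
hard itemset budget — the intended universe is a dozen curated diagnosis
categories, not raw codes.

Definitions, for a transaction multiset ``T`` of size ``n`` over items
``I`` and disjoint itemsets ``X`` (antecedent) and ``Y`` (consequent)::

    support(Z)   = |{t in T : Z subset t}| / n
    confidence   = support(X u Y) / support(X)        (= P(Y|X))
    lift         = confidence / support(Y)            (= P(X,Y) / P(X)P(Y))

Lift is symmetric in ``X`` and ``Y``; it exceeds 1 exactly when the joint
support exceeds the product of the marginal supports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TransactionSet",
    "Rule",
    "MiningConfig",
    "support",
    "confidence",
    "lift",
    "mine_rules",
    "rule_label",
]


class TransactionSet:
    """Transactions encoded as bitmasks over an ordered item universe.

    The universe is limited to 64 items; the analysis universe here is a
    handful of curated diagnosis categories.
    """

    def __init__(self, transactions: Sequence[Iterable[str]], universe: Sequence[str] | None = None):
        tx = [frozenset(t) for t in transactions]
        if universe is None:
            universe = sorted(set().union(*tx) if tx else set())
        self.universe: tuple[str, ...] = tuple(universe)
        if len(self.universe) > 64:
            raise ValueError(
                f"item universe of {len(self.universe)} exceeds 64; "
                "constrain the universe to curated categories"
            )
        extra = set().union(*tx, set()) - set(self.universe)
        if extra:
            raise ValueError(f"transactions contain items outside the universe: {sorted(extra)}")
        self._index = {item: i for i, item in enumerate(self.universe)}
        self.transactions: list[frozenset] = tx
        self.masks = np.array(
            [self._mask(t) for t in tx], dtype=np.uint64
        )
        self.n = len(tx)

    def _mask(self, itemset: Iterable[str]) -> int:
        m = 0
        for item in itemset:
            m |= 1 << self._index[item]
        return m

    def count(self, itemset: Iterable[str]) -> int:
        m = np.uint64(self._mask(itemset))
        return int(np.count_nonzero((self.masks & m) == m))

    def support(self, itemset: Iterable[str]) -> float:
        if self.n == 0:
            raise ValueError("support is undefined on an empty transaction set")
        return self.count(itemset) / self.n

    @classmethod
    def from_frame(cls, transactions: pd.DataFrame, universe: Sequence[str] | None = None,
                   items_col: str = "items") -> "TransactionSet":
        return cls(list(transactions[items_col]), universe=universe)


@dataclass(frozen=True)
class Rule:
    """An association rule ``X -> Y`` with its metrics on a transaction set."""

    antecedent: frozenset
    consequent: frozenset
    support: float
    confidence: float
    lift: float

    def __post_init__(self) -> None:
        if self.antecedent & self.consequent:
            raise ValueError("antecedent and consequent must be disjoint")

    @property
    def relations(self) -> int:
        return len(self.antecedent) + len(self.consequent)

    @property
    def label(self) -> str:
        return rule_label(self.antecedent, self.consequent)


def rule_label(antecedent: Iterable[str], consequent: Iterable[str]) -> str:
    return (
        " & ".join(sorted(antecedent)) + " => " + " & ".join(sorted(consequent))
    )


@dataclass(frozen=True)
class MiningConfig:
    """Mining thresholds; defaults give the lift-only top-k regime with
    consequents of two or three items."""

    minsup: float = 0.0
    minconf: float = 0.0
    min_lift: float = 1.0
    k: int = 10_000
    antecedent_constraint: frozenset | None = None
    consequent_sizes: frozenset = frozenset({2, 3})
    max_rule_size: int = 4
    itemset_budget: int = 2_000_000

    def __post_init__(self) -> None:
        if not (0.0 <= self.minsup <= 1.0 and 0.0 <= self.minconf <= 1.0):
            raise ValueError("minsup and minconf must lie in [0, 1]")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.max_rule_size < 2:
            raise ValueError("max_rule_size must be >= 2")


def support(itemset: Iterable[str], ts: TransactionSet) -> float:
    """Fraction of transactions containing ``itemset`` (1.0 for the empty set)."""
    return ts.support(itemset)


def confidence(antecedent: Iterable[str], consequent: Iterable[str], ts: TransactionSet) -> float:
    """P(consequent | antecedent); undefined (ValueError) when the antecedent
    has zero support."""
    nx = ts.count(antecedent)
    if nx == 0:
        raise ValueError("confidence undefined: antecedent has zero support")
    return ts.count(set(antecedent) | set(consequent)) / nx


def lift(antecedent: Iterable[str], consequent: Iterable[str], ts: TransactionSet) -> float:
    """confidence / support(consequent); symmetric in its arguments."""
    sy = ts.count(consequent)
    if sy == 0:
        raise ValueError("lift undefined: consequent has zero support")
    return confidence(antecedent, consequent, ts) * ts.n / sy


def _sort_key(r: Rule):
    return (-r.lift, -r.support, -r.confidence, r.label)


def mine_rules(ts: TransactionSet, config: MiningConfig = MiningConfig()) -> list[Rule]:
    """Level-wise enumeration of itemsets up to ``max_rule_size`` followed by
    rule generation and filtering.

    Rules must satisfy ``support >= minsup``, ``confidence >= minconf`` and
    ``lift > min_lift`` (strict); when an antecedent constraint is set only
    rules with exactly that antecedent are kept, and consequent sizes are
    restricted to ``consequent_sizes``.  Output is sorted by
    (lift desc, support desc, confidence desc, label) and truncated to ``k``.
    """
    if ts.n == 0:
        raise ValueError("cannot mine an empty transaction set")
    items = ts.universe
    L = min(config.max_rule_size, len(items))
    n_itemsets = sum(comb(len(items), s) for s in range(1, L + 1))
    if n_itemsets > config.itemset_budget:
        raise ValueError(
            f"level-wise enumeration would visit {n_itemsets} itemsets "
            f"(budget {config.itemset_budget}); constrain the item universe "
            "or lower max_rule_size"
        )

    counts: dict[frozenset, int] = {}
    for size in range(1, L + 1):
        for combo in combinations(items, size):
            fs = frozenset(combo)
            counts[fs] = ts.count(fs)

    n = ts.n
    constraint = config.antecedent_constraint
    if constraint is not None:
        constraint = frozenset(constraint)

    rules: list[Rule] = []
    for z, nz in counts.items():
        if len(z) < 2:
            continue
        if constraint is not None:
            if not constraint < z:
                continue
            x_candidates = [constraint]
        else:
            x_candidates = [
                frozenset(c)
                for size in range(1, len(z))
                for c in combinations(sorted(z), size)
            ]
        for x in x_candidates:
            y = z - x
            if len(y) not in config.consequent_sizes:
                continue
            nx, ny = counts[x], counts[y]
            if nx == 0 or ny == 0:
                continue  # metrics undefined
            s = nz / n
            c = nz / nx
            lf = c * n / ny
            if s >= config.minsup and c >= config.minconf and lf > config.min_lift:
                rules.append(Rule(x, y, s, c, lf))

    rules.sort(key=_sort_key)
    return rules[: config.k]


def rules_to_frame(rules: Sequence[Rule]) -> pd.DataFrame:
    """Tabular view of a rule list."""
    return pd.DataFrame(
        [
            {
                "relations": r.relations,
                "support": r.support,
                "confidence": r.confidence,
                "lift": r.lift,
                "antecedent": " & ".join(sorted(r.antecedent)),
                "consequent": " & ".join(sorted(r.consequent)),
            }
            for r in rules
        ],
        columns=["relations", "support", "confidence", "lift", "antecedent", "consequent"],
    )
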