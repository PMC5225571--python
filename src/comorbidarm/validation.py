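"""Train/test partitioning of the cohort and held-out re-evaluation of
mined rules, with per-rule case-control odds ratios.

The split is stratified by case/control group so that the 1:4 ratio is
preserved in both partitions (292/1168 members split two-thirds/one-third
gives 195/779 training and 97/389 testing members).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .arm import Rule, TransactionSet
from .contingency_stats import OrEstimate, TwoByTwo, odds_ratio

__all__ = ["SplitSpec", "RuleEvaluation", "split_cohort", "evaluate_rule"]


@dataclass(frozen=True)
class SplitSpec:
    """Person-level stratified random partition."""

    train_fraction: float = 2 / 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")


def split_cohort(
    table: pd.DataFrame, spec: SplitSpec, group_col: str = "group"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition rows into train/test, stratified by ``group_col``.

    Within each group, ``round(train_fraction * n_group)`` members are drawn
    uniformly at random into the training partition.  Raises if either
    partition would lose a group entirely.
    """
    if table.empty:
        raise ValueError("cannot split an empty cohort")
    rng = np.random.default_rng(spec.seed)
    train_parts, test_parts = [], []
    for g in sorted(pd.unique(table[group_col])):
        grp = table[table[group_col] == g].sort_values("person_id")
        n = len(grp)
        n_train = int(np.floor(spec.train_fraction * n + 0.5))
        if n_train == 0 or n_train == n:
            raise ValueError(
                f"split leaves group {g!r} empty on one side "
                f"({n_train} of {n} in training)"
            )
        perm = rng.permutation(n)
        train_parts.append(grp.iloc[perm[:n_train]])
        test_parts.append(grp.iloc[perm[n_train:]])
    train = pd.concat(train_parts).sort_values("person_id").reset_index(drop=True)
    test = pd.concat(test_parts).sort_values("person_id").reset_index(drop=True)
    return train, test


@dataclass(frozen=True)
class RuleEvaluation:
    """A rule's metrics on one evaluation set, plus the case-control 2x2
    for carrying the full consequent."""

    rule: Rule
    support: float
    confidence: float
    lift: float
    n_cases_with: int
    n_controls_with: int
    n_cases: int
    n_controls: int
    or_estimate: OrEstimate


def evaluate_rule(
    rule: Rule,
    transactions: pd.DataFrame,
    index_item: str = "BPD",
    level: float = 0.95,
) -> RuleEvaluation:
    """Recompute a rule's support/confidence/lift on ``transactions`` and
    estimate the case-control odds ratio of carrying its consequent.

    The rule's antecedent must be the singleton index item; consequent
    exposure then coincides with full-rule exposure among cases.
    """
    if rule.antecedent != frozenset({index_item}):
        raise ValueError(
            f"evaluate_rule expects antecedent {{{index_item!r}}}, "
            f"got {sorted(rule.antecedent)}"
        )
    ts = TransactionSet.from_frame(
        transactions,
        universe=sorted(
            set().union(*transactions["items"], rule.antecedent, rule.consequent)
        ),
    )
    nz = ts.count(rule.antecedent | rule.consequent)
    nx = ts.count(rule.antecedent)
    ny = ts.count(rule.consequent)
    s = nz / ts.n
    c = nz / nx if nx else float("nan")
    lf = c * ts.n / ny if nx and ny else float("nan")

    is_case = transactions["group"] == "case"
    has_y = np.array([rule.consequent <= t for t in transactions["items"]])
    a = int((is_case & has_y).sum())
    b = int((~is_case & has_y).sum())
    n_cases = int(is_case.sum())
    n_controls = int((~is_case).sum())
    t = TwoByTwo(a=a, b=b, c=n_cases - a, d=n_controls - b,
                 exposure=" & ".join(sorted(rule.consequent)))
    return RuleEvaluation(
        rule=rule,
        support=s,
        confidence=c,
        lift=lf,
        n_cases_with=a,
        n_controls_with=b,
        n_cases=n_cases,
        n_controls=n_controls,
        or_estimate=odds_ratio(t, level=level),
    )
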