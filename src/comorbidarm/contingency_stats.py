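"""2x2 tables, odds ratios with Wald confidence intervals, and demographic
group comparisons.

The odds ratio is the cross-product ratio ``(a*d)/(b*c)``, which for a single
binary predictor coincides with the exponentiated coefficient of a
univariable logistic regression of group on exposure.  A table with any zero
cell yields an *undefined* estimate (rendered ``--``) unless the
Haldane-Anscombe +0.5 continuity correction is requested.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TwoByTwo",
    "OrEstimate",
    "two_by_two",
    "odds_ratio",
    "compare_demographics",
    "median_iqr",
    "format_or",
    "UNDEFINED_MARK",
]

UNDEFINED_MARK = "--"

#: Age bands used for the banded age comparison.
AGE_BANDS = ((0, 19), (20, 39), (40, 59), (60, 200))


@dataclass(frozen=True)
class TwoByTwo:
    """Exposure counts: ``a``/``c`` exposed/unexposed in group 1, ``b``/``d``
    exposed/unexposed in group 2."""

    a: int
    b: int
    c: int
    d: int
    group_labels: tuple[str, str] = ("case", "control")
    exposure: str = "exposed"

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")

    def swap_groups(self) -> "TwoByTwo":
        return TwoByTwo(
            self.b, self.a, self.d, self.c, self.group_labels[::-1], self.exposure
        )


@dataclass(frozen=True)
class OrEstimate:
    """Odds ratio with a Wald CI; ``nan`` values mean "undefined" (zero
    cell, rendered ``--``)."""

    or_value: float
    ci_low: float
    ci_high: float
    level: float = 0.95

    @property
    def defined(self) -> bool:
        return math.isfinite(self.or_value)

    @property
    def significant(self) -> bool:
        return self.defined and (self.ci_low > 1.0 or self.ci_high < 1.0)


def two_by_two(
    table: pd.DataFrame,
    category: str,
    group_col: str = "group",
    groups: tuple[str, str] = ("case", "control"),
    items_col: str = "items",
) -> TwoByTwo:
    """Tabulate exposure to ``category`` across two disjoint groups of a
    transactions-style DataFrame (one row per person, ``items`` a set)."""
    g1 = table[table[group_col] == groups[0]]
    g2 = table[table[group_col] == groups[1]]
    if len(g1) == 0 or len(g2) == 0:
        raise ValueError(f"empty group among {groups} in column {group_col!r}")
    a = int(sum(category in s for s in g1[items_col]))
    b = int(sum(category in s for s in g2[items_col]))
    return TwoByTwo(
        a=a, b=b, c=len(g1) - a, d=len(g2) - b,
        group_labels=groups, exposure=category,
    )


def odds_ratio(
    t: TwoByTwo, level: float = 0.95, continuity: bool = False
) -> OrEstimate:
    """Cross-product odds ratio with Wald (log-scale normal) CI.

    Any zero cell makes the estimate undefined unless ``continuity`` adds
    0.5 to every cell (Haldane-Anscombe), which keeps the estimate finite
    for any table with positive margins.
    """
    a, b, c, d = (float(x) for x in (t.a, t.b, t.c, t.d))
    if continuity:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if min(a, b, c, d) == 0:
        return OrEstimate(float("nan"), float("nan"), float("nan"), level)
    z = stats.norm.ppf(1 - (1 - level) / 2)
    log_or = math.log(a * d / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return OrEstimate(
        or_value=math.exp(log_or),
        ci_low=math.exp(log_or - z * se),
        ci_high=math.exp(log_or + z * se),
        level=level,
    )


def format_or(value: float) -> str:
    """Report-style rendering: 3 significant figures, integers at >= 100,
    ``--`` when undefined."""
    if value is None or not math.isfinite(value):
        return UNDEFINED_MARK
    if value == 0:
        return "0"
    rounded = float(f"{value:.3g}")
    if rounded >= 100:
        return f"{rounded:.0f}"
    return f"{rounded:g}"


def compare_demographics(members: pd.DataFrame, group_col: str = "group") -> dict:
    """P values for demographic balance between the two groups of a cohort
    members table: chi-squared for sex and for banded age, two-sample t for
    age.  Degenerate (single-category) variables report P = 1 with a
    warning."""
    groups = list(pd.unique(members[group_col]))
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, got {groups}")
    for g in groups:
        if (members[group_col] == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 members")

    out: dict[str, float] = {}

    def _chi2_p(crosstab: pd.DataFrame, label: str) -> float:
        if crosstab.shape[0] < 2:
            warnings.warn(f"{label}: single-category variable, reporting P = 1")
            return 1.0
        chi2, p, _, _ = stats.chi2_contingency(crosstab.to_numpy(), correction=False)
        return 1.0 if chi2 == 0 else float(p)

    out["sex_p"] = _chi2_p(
        pd.crosstab(members["sex"], members[group_col]), "sex"
    )

    a1 = members.loc[members[group_col] == groups[0], "age"].to_numpy(dtype=float)
    a2 = members.loc[members[group_col] == groups[1], "age"].to_numpy(dtype=float)
    if np.ptp(np.concatenate([a1, a2])) == 0:
        warnings.warn("age: constant variable, reporting P = 1")
        out["age_t_p"] = 1.0
    else:
        tstat, p = stats.ttest_ind(a1, a2)
        out["age_t_p"] = 1.0 if tstat == 0 else float(p)

    bands = pd.cut(
        members["age"],
        bins=[b[0] - 0.5 for b in AGE_BANDS] + [AGE_BANDS[-1][1] + 0.5],
        labels=[f"{lo}-{hi}" for lo, hi in AGE_BANDS],
    )
    out["age_band_p"] = _chi2_p(
        pd.crosstab(bands, members[group_col], dropna=True), "age bands"
    )
    return out


def median_iqr(ages) -> tuple[float, float, float]:
    """Median and 25th/75th percentiles (linear interpolation)."""
    x = np.asarray(list(ages), dtype=float)
    if x.size == 0:
        raise ValueError("median_iqr requires a non-empty sequence")
    med, q1, q3 = np.percentile(x, [50, 25, 75])
    return float(med), float(q1), float(q3)
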