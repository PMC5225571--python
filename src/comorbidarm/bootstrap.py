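"""Matched bootstrap validation of association rules.

Each replicate draws the cases with replacement (duplicates retained as
distinct transactions), re-matches ``ratio`` exact age/sex controls per
drawn case from the eligible pool (without replacement within a case's
draw, with replacement across case instances and replicates), rebuilds the
transactions, and re-evaluates every input rule.  Per-rule means and
percentile confidence intervals are aggregated over the B replicates;
replicates in which a rule's odds ratio is undefined (zero cell) are
excluded from the OR mean and CI, with the count of defined replicates
reported.

Two intervals are reported per metric: the percentile interval of the
replicate distribution (order statistics at 2.5%/97.5%; describes
replicate-to-replicate spread and drives the significance flags) and the
normal-approximation confidence interval of the *mean* metric
(``mean +/- z * sd / sqrt(B)``), whose width shrinks as ``1/sqrt(B)`` and
which matches how bootstrap-mean tables are conventionally printed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .arm import Rule
from .cohort import MatchingError, age_at
from .icd_categories import CategoryMap, person_category_set

__all__ = [
    "BootstrapConfig",
    "BootstrapSummary",
    "bootstrap_rules",
    "percentile_ci",
    "mean_ci",
    "summaries_to_frame",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class BootstrapConfig:
    B: int = 1000
    ratio: int = 4
    seed: int = 0
    ci_level: float = 0.95
    window_years: float = 3
    #: draw cases with replacement; False evaluates the original case set in
    #: every replicate (degenerate diagnostic mode)
    resample_cases: bool = True

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if self.ratio < 1:
            raise ValueError("ratio must be >= 1")


@dataclass(frozen=True)
class BootstrapSummary:
    """Per-rule aggregate over B replicates."""

    rule: Rule
    mean_support: float
    ci_support: tuple[float, float]
    mean_confidence: float
    ci_confidence: tuple[float, float]
    mean_lift: float
    ci_lift: tuple[float, float]
    mean_or: float
    ci_or: tuple[float, float]
    n_defined_or: int
    significant_lift: bool
    significant_or: bool
    n_replicates: int
    #: normal-approximation CIs of the mean metric (mean +/- z*sd/sqrt(B))
    mean_ci_support: tuple[float, float] = (float("nan"), float("nan"))
    mean_ci_confidence: tuple[float, float] = (float("nan"), float("nan"))
    mean_ci_lift: tuple[float, float] = (float("nan"), float("nan"))
    mean_ci_or: tuple[float, float] = (float("nan"), float("nan"))


def percentile_ci(values, level: float = 0.95) -> tuple[float, float]:
    """Percentile interval whose endpoints are order statistics of the
    replicate vector: the ceil(alpha/2*B)-th smallest and the
    ceil((1-alpha/2)*B)-th smallest value."""
    v = np.sort(np.asarray(values, dtype=float))
    m = v.size
    if m == 0:
        return (float("nan"), float("nan"))
    alpha = 1.0 - level
    # round before ceil so float noise cannot skip past an exact boundary
    # (e.g. 0.025 * 1000 must select the 25th order statistic)
    lo = max(math.ceil(round(alpha / 2 * m, 9)) - 1, 0)
    hi = min(math.ceil(round((1 - alpha / 2) * m, 9)) - 1, m - 1)
    return float(v[lo]), float(v[hi])


def mean_ci(values, level: float = 0.95) -> tuple[float, float]:
    """Normal-approximation CI for the mean of the replicate vector."""
    from scipy.stats import norm

    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        return (float("nan"), float("nan"))
    z = norm.ppf(1 - (1 - level) / 2)
    half = z * v.std(ddof=1) / math.sqrt(v.size) if v.size > 1 else 0.0
    m = float(v.mean())
    return (m - half, m + half)


def _excludes_one(ci: tuple[float, float]) -> bool:
    lo, hi = ci
    return math.isfinite(lo) and math.isfinite(hi) and (lo > 1.0 or hi < 1.0)


def bootstrap_rules(
    cases: pd.DataFrame,
    control_pool: pd.DataFrame,
    diagnoses: pd.DataFrame,
    rules: list[Rule],
    cmap: CategoryMap,
    cfg: BootstrapConfig = BootstrapConfig(),
) -> list[BootstrapSummary]:
    """Matched-bootstrap aggregation of rule metrics.

    Parameters
    ----------
    cases
        Incident cases, columns ``person_id, index_date, sex, birth_date``.
    control_pool
        Candidate controls (must exclude index-code carriers), columns
        ``person_id, sex, birth_date``.
    diagnoses
        Full diagnosis records for everyone involved.
    rules
        Rules with antecedent equal to the index-item singleton.
    """
    if not rules:
        raise ValueError("rules must be non-empty")
    index_item = cmap.index_label
    for r in rules:
        if r.antecedent != frozenset({index_item}):
            raise ValueError(f"rule {r.label!r} antecedent is not the index item")

    rng = np.random.default_rng(cfg.seed)
    cases = cases.sort_values("person_id").reset_index(drop=True)
    n_cases = len(cases)
    if n_cases == 0:
        raise ValueError("no cases to resample")

    consequents = [r.consequent for r in rules]
    relevant_items = frozenset().union(*consequents)

    by_person = {
        pid: list(zip(grp["icd9_code"], grp["diagnosis_date"]))
        for pid, grp in diagnoses.groupby("person_id", sort=False)
    }

    def _items(pid: str, index_date) -> frozenset:
        return frozenset(
            person_category_set(
                by_person.get(pid, ()), index_date, cfg.window_years, cmap,
                items=relevant_items,
            )
        )

    n_rules = len(rules)
    # per original case: does its transaction carry each rule's consequent?
    case_has = np.zeros((n_cases, n_rules), dtype=bool)
    case_dates = list(pd.DatetimeIndex(cases["index_date"]))
    for i, (pid, idx_date) in enumerate(zip(cases["person_id"], case_dates)):
        items = _items(pid, idx_date)
        case_has[i] = [y <= items for y in consequents]

    # eligible pool rows per case (exact sex + integer age at the case's
    # index date)
    pool = control_pool.reset_index(drop=True)
    pool_sex = pool["sex"].to_numpy()
    pb = pd.DatetimeIndex(pool["birth_date"])
    pool_year, pool_md = pb.year.values, pb.month.values * 100 + pb.day.values
    case_sex = cases["sex"].to_numpy()
    case_age = age_at(cases["index_date"], cases["birth_date"])
    eligible: list[np.ndarray] = []
    for i, idx_date in enumerate(case_dates):
        md = idx_date.month * 100 + idx_date.day
        pool_age = (idx_date.year - pool_year) - (md < pool_md).astype(int)
        elig = np.flatnonzero((pool_sex == case_sex[i]) & (pool_age == case_age[i]))
        if elig.size < cfg.ratio:
            raise MatchingError(
                f"case {cases['person_id'].iloc[i]} has only {elig.size} "
                f"eligible controls for ratio {cfg.ratio}"
            )
        eligible.append(elig)

    control_cache: dict[tuple[int, int], np.ndarray] = {}

    def _control_has(pool_row: int, case_i: int) -> np.ndarray:
        key = (pool_row, case_i)
        out = control_cache.get(key)
        if out is None:
            items = _items(pool["person_id"].iloc[pool_row], case_dates[case_i])
            out = np.array([y <= items for y in consequents], dtype=bool)
            control_cache[key] = out
        return out

    n_total = n_cases * (1 + cfg.ratio)
    sup = np.empty((cfg.B, n_rules))
    conf = np.empty((cfg.B, n_rules))
    lft = np.empty((cfg.B, n_rules))
    orr = np.empty((cfg.B, n_rules))

    for b in range(cfg.B):
        if cfg.resample_cases:
            draw = rng.integers(0, n_cases, n_cases)
        else:
            draw = np.arange(n_cases)
        a = case_has[draw].sum(axis=0).astype(float)
        bcount = np.zeros(n_rules)
        for i in draw:
            elig = eligible[i]
            picks = rng.choice(elig, size=cfg.ratio, replace=False)
            for j in picks:
                bcount += _control_has(int(j), int(i))
        n_ctrl = n_cases * cfg.ratio
        sup[b] = a / n_total
        conf[b] = a / n_cases
        with np.errstate(divide="ignore", invalid="ignore"):
            lft[b] = np.where(a + bcount > 0, conf[b] * n_total / (a + bcount), np.nan)
        c_cell = n_cases - a
        d_cell = n_ctrl - bcount
        cells = np.stack([a, bcount, c_cell, d_cell])
        with np.errstate(divide="ignore", invalid="ignore"):
            orr[b] = np.where(
                (cells > 0).all(axis=0), a * d_cell / (bcount * c_cell), np.nan
            )

    out = []
    for r_i, rule in enumerate(rules):
        or_vals = orr[:, r_i]
        defined = or_vals[np.isfinite(or_vals)]
        lift_vals = lft[:, r_i]
        lift_def = lift_vals[np.isfinite(lift_vals)]
        ci_or = percentile_ci(defined, cfg.ci_level) if defined.size else (float("nan"),) * 2
        ci_lift = percentile_ci(lift_def, cfg.ci_level) if lift_def.size else (float("nan"),) * 2
        out.append(
            BootstrapSummary(
                rule=rule,
                mean_support=float(sup[:, r_i].mean()),
                ci_support=percentile_ci(sup[:, r_i], cfg.ci_level),
                mean_confidence=float(conf[:, r_i].mean()),
                ci_confidence=percentile_ci(conf[:, r_i], cfg.ci_level),
                mean_lift=float(lift_def.mean()) if lift_def.size else float("nan"),
                ci_lift=ci_lift,
                mean_or=float(defined.mean()) if defined.size else float("nan"),
                ci_or=ci_or,
                n_defined_or=int(defined.size),
                significant_lift=_excludes_one(ci_lift),
                significant_or=_excludes_one(ci_or),
                n_replicates=cfg.B,
                mean_ci_support=mean_ci(sup[:, r_i], cfg.ci_level),
                mean_ci_confidence=mean_ci(conf[:, r_i], cfg.ci_level),
                mean_ci_lift=mean_ci(lift_vals, cfg.ci_level),
                mean_ci_or=mean_ci(or_vals, cfg.ci_level),
            )
        )
    return out


def summaries_to_frame(summaries: list[BootstrapSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        rows.append(
            {
                "relations": s.rule.relations,
                "rule": s.rule.label,
                "mean_support": s.mean_support,
                "support_ci_low": s.ci_support[0],
                "support_ci_high": s.ci_support[1],
                "mean_confidence": s.mean_confidence,
                "confidence_ci_low": s.ci_confidence[0],
                "confidence_ci_high": s.ci_confidence[1],
                "mean_lift": s.mean_lift,
                "lift_ci_low": s.ci_lift[0],
                "lift_ci_high": s.ci_lift[1],
                "mean_or": s.mean_or,
                "or_ci_low": s.ci_or[0],
                "or_ci_high": s.ci_or[1],
                "n_defined_or": s.n_defined_or,
                "significant_lift": s.significant_lift,
                "significant_or": s.significant_or,
                "mean_support_ci_low": s.mean_ci_support[0],
                "mean_support_ci_high": s.mean_ci_support[1],
                "mean_lift_ci_low": s.mean_ci_lift[0],
                "mean_lift_ci_high": s.mean_ci_lift[1],
                "mean_or_ci_low": s.mean_ci_or[0],
                "mean_or_ci_high": s.mean_ci_or[1],
            }
        )
    return pd.DataFrame(rows)
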