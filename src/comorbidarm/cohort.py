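"""Incident-case selection, 1:4 age/sex-matched control sampling, and the
transaction table used for rule mining.

Matching conventions
--------------------
* A case is a person whose *first* index-disorder code falls inside the
  enrollment window; an earlier code anywhere in the record disqualifies
  (incidence requirement).
* Controls are drawn uniformly at random, without replacement across the
  whole cohort, from pool members with identical sex and identical integer
  age at the case's index date.  Any person ever carrying the index code is
  excluded from the pool.
* Each control inherits its matched case's index date, which anchors the
  +/-3-year comorbidity window (the standard matched-design convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .icd_categories import CategoryMap, person_category_set

__all__ = [
    "Cohort",
    "MatchingError",
    "select_cases",
    "filter_complete_cases",
    "match_controls",
    "build_transactions",
    "age_at",
]

log = logging.getLogger(__name__)


class MatchingError(RuntimeError):
    """Raised when a case has too few eligible controls."""


@dataclass
class Cohort:
    """Matched case-control cohort.

    ``members`` has columns ``person_id``, ``group`` ("case"/"control"),
    ``matched_case_id`` (empty for cases), ``sex``, ``age`` (integer years at
    the anchoring index date) and ``index_date``.
    """

    members: pd.DataFrame
    match_ratio: int
    seed: int

    @property
    def cases(self) -> pd.DataFrame:
        return self.members[self.members["group"] == "case"]

    @property
    def controls(self) -> pd.DataFrame:
        return self.members[self.members["group"] == "control"]


def age_at(dates, birth_dates) -> np.ndarray:
    """Completed age in whole years at ``dates`` (vectorised)."""
    d = pd.DatetimeIndex(np.atleast_1d(np.asarray(dates, dtype="datetime64[ns]")))
    b = pd.DatetimeIndex(np.atleast_1d(np.asarray(birth_dates, dtype="datetime64[ns]")))
    years = d.year.values - b.year.values
    before_birthday = (d.month.values * 100 + d.day.values) < (
        b.month.values * 100 + b.day.values
    )
    return years - before_birthday.astype(int)


def select_cases(
    diagnoses: pd.DataFrame,
    enrollment_window: tuple,
    index_code: str = "301.83",
) -> pd.DataFrame:
    """Persons whose first occurrence of ``index_code`` falls inside the
    window; that first date becomes the index date.

    Returns a DataFrame ``person_id, index_date`` sorted by person.
    """
    start, end = (pd.Timestamp(d) for d in enrollment_window)
    if end < start:
        raise ValueError("enrollment window is empty")
    hits = diagnoses[diagnoses["icd9_code"] == index_code]
    if hits.empty:
        return pd.DataFrame(columns=["person_id", "index_date"])
    first = hits.groupby("person_id", sort=True)["diagnosis_date"].min()
    first = first[(first >= start) & (first <= end)]
    return first.rename("index_date").reset_index()


def filter_complete_cases(
    persons: pd.DataFrame, required_fields: list[str] | None = None
) -> pd.DataFrame:
    """Drop persons with any required demographic field missing
    (complete-case analysis under a missing-completely-at-random assumption).
    """
    required = required_fields or ["person_id", "sex", "birth_date"]
    mask = persons[required].notna().all(axis=1)
    dropped = int((~mask).sum())
    if dropped:
        log.info("complete-case filter dropped %d of %d persons", dropped, len(persons))
    return persons[mask].reset_index(drop=True)


def match_controls(
    cases: pd.DataFrame,
    pool: pd.DataFrame,
    ratio: int = 4,
    rng_seed: int = 0,
    age_band: int = 0,
    on_insufficient: str = "error",
) -> Cohort:
    """Draw ``ratio`` exact age/sex-matched controls per case.

    Parameters
    ----------
    cases
        Columns ``person_id, index_date, sex, birth_date``.
    pool
        Candidate controls (``person_id, sex, birth_date``); must already
        exclude every index-code carrier.
    age_band
        0 requires identical integer age; with ``on_insufficient="relax"``
        the match is widened to +/-``age_band`` years for cases that cannot
        be matched exactly (each relaxation is logged).
    """
    if ratio < 1:
        raise ValueError("ratio must be a positive integer")
    rng = np.random.default_rng(rng_seed)

    cases = cases.sort_values("person_id").reset_index(drop=True)
    case_rows = []
    for _, c in cases.iterrows():
        case_rows.append(
            {
                "person_id": c["person_id"],
                "group": "case",
                "matched_case_id": "",
                "sex": c["sex"],
                "age": int(age_at(c["index_date"], c["birth_date"])[0]),
                "index_date": pd.Timestamp(c["index_date"]),
            }
        )

    pool = pool.reset_index(drop=True)
    pool_pid = pool["person_id"].to_numpy()
    pool_sex = pool["sex"].to_numpy()
    pb = pd.DatetimeIndex(pool["birth_date"])
    pool_year, pool_md = pb.year.values, pb.month.values * 100 + pb.day.values
    used = np.zeros(len(pool), dtype=bool)

    control_rows = []
    for crow in case_rows:
        idx_date = crow["index_date"]
        md = idx_date.month * 100 + idx_date.day
        pool_age = (idx_date.year - pool_year) - (md < pool_md).astype(int)
        for band in range(0, age_band + 1):
            eligible = np.flatnonzero(
                (pool_sex == crow["sex"])
                & (np.abs(pool_age - crow["age"]) <= band)
                & ~used
            )
            if eligible.size >= ratio:
                if band > 0:
                    log.warning(
                        "case %s matched with relaxed age band +/-%d",
                        crow["person_id"],
                        band,
                    )
                break
        else:
            eligible = np.array([], dtype=int)
        if eligible.size < ratio:
            raise MatchingError(
                f"case {crow['person_id']} (sex={crow['sex']}, age={crow['age']}): "
                f"only {eligible.size} eligible controls for ratio {ratio}"
            )
        if on_insufficient not in ("error", "relax"):
            raise ValueError(f"unknown insufficiency policy {on_insufficient!r}")
        chosen = np.sort(rng.choice(eligible, size=ratio, replace=False))
        used[chosen] = True
        for j in chosen:
            control_rows.append(
                {
                    "person_id": pool_pid[j],
                    "group": "control",
                    "matched_case_id": crow["person_id"],
                    "sex": pool_sex[j],
                    "age": int(pool_age[j]),
                    "index_date": idx_date,
                }
            )

    members = pd.DataFrame(
        case_rows + control_rows,
        columns=["person_id", "group", "matched_case_id", "sex", "age", "index_date"],
    )
    dup = members["person_id"].duplicated()
    if dup.any():
        raise MatchingError(
            f"person {members.loc[dup, 'person_id'].iloc[0]!r} appears twice in cohort"
        )
    return Cohort(members=members.reset_index(drop=True), match_ratio=ratio, seed=rng_seed)


def build_transactions(
    cohort: Cohort,
    diagnoses: pd.DataFrame,
    cmap: CategoryMap,
    window_years: float = 3,
    items: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """One transaction per cohort member: the index item (cases only) plus
    the member's category set within the comorbidity window.

    ``items`` restricts the comorbidity labels kept (e.g. the mining
    universe); ``None`` keeps every label the map produces.  Rows are ordered
    by ``person_id``.
    """
    members = cohort.members.sort_values("person_id").reset_index(drop=True)
    by_person = {
        pid: grp[["icd9_code", "diagnosis_date"]]
        for pid, grp in diagnoses.groupby("person_id", sort=False)
    }
    empty = pd.DataFrame(columns=["icd9_code", "diagnosis_date"])
    rows = []
    for _, m in members.iterrows():
        cats = person_category_set(
            by_person.get(m["person_id"], empty),
            m["index_date"],
            window_years,
            cmap,
            items=items,
        )
        cats.discard(cmap.index_label)
        if m["group"] == "case":
            cats.add(cmap.index_label)
        rows.append(
            {"person_id": m["person_id"], "group": m["group"], "items": frozenset(cats)}
        )
    return pd.DataFrame(rows, columns=["person_id", "group", "items"])
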