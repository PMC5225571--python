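import numpy as np
import pandas as pd
import pytest

from comorbidarm.cohort import (
    MatchingError,
    build_transactions,
    filter_complete_cases,
    match_controls,
    select_cases,
)
from comorbidarm.icd_categories import person_category_set


def _diag(rows):
    df = pd.DataFrame(rows, columns=["person_id", "icd9_code", "diagnosis_date"])
    df["diagnosis_date"] = pd.to_datetime(df["diagnosis_date"])
    return df


WINDOW = ("2003-01-01", "2006-12-31")


class TestSelectCases:
    def test_first_occurrence_rules(self):
        diag = _diag(
            [
                # first index code inside the window -> included at that date
                ("P1", "301.83", "2004-05-01"),
                ("P1", "301.83", "2005-01-01"),
                # index code before the window and again inside -> excluded
                ("P2", "301.83", "2001-03-01"),
                ("P2", "301.83", "2004-03-01"),
                # never carries the index code -> excluded
                ("P3", "296.2", "2004-06-01"),
                # boundary: first code on the window start day -> included
                ("P4", "301.83", "2003-01-01"),
            ]
        )
        got = select_cases(diag, WINDOW)
        assert list(got["person_id"]) == ["P1", "P4"]
        assert got.set_index("person_id")["index_date"]["P1"] == pd.Timestamp("2004-05-01")

    def test_no_cases(self):
        got = select_cases(_diag([("P1", "486", "2004-01-01")]), WINDOW)
        assert got.empty

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            select_cases(_diag([]), ("2005-01-01", "2004-01-01"))


class TestCompleteCase:
    def test_identity_when_complete(self):
        persons = pd.DataFrame(
            {"person_id": ["a", "b"], "sex": ["female", "male"],
             "birth_date": pd.to_datetime(["1980-01-01", "1990-01-01"])}
        )
        pd.testing.assert_frame_equal(filter_complete_cases(persons), persons)

    def test_drops_missing(self):
        persons = pd.DataFrame(
            {"person_id": ["a", "b", "c"], "sex": ["female", None, "male"],
             "birth_date": pd.to_datetime(["1980-01-01", "1990-01-01", None])}
        )
        assert list(filter_complete_cases(persons)["person_id"]) == ["a"]


class TestMatching:
    def test_counts_and_exact_marginals(self, cohort_bundle):
        cohort = cohort_bundle["cohort"]
        cases, controls = cohort.cases, cohort.controls
        assert len(controls) == 4 * len(cases)
        # sex and age marginals equal exactly
        assert controls["sex"].value_counts().eq(
            cases["sex"].value_counts() * 4
        ).all()
        assert sorted(controls["age"]) == sorted(np.repeat(sorted(cases["age"]), 4))
        # per matched set: identical sex and age
        merged = controls.merge(
            cases, left_on="matched_case_id", right_on="person_id",
            suffixes=("_ctl", "_case"),
        )
        assert (merged["sex_ctl"] == merged["sex_case"]).all()
        assert (merged["age_ctl"] == merged["age_case"]).all()
        assert (merged["index_date_ctl"] == merged["index_date_case"]).all()
        assert not cohort.members["person_id"].duplicated().any()

    def test_seed_determinism(self, cohort_bundle):
        again = match_controls(
            cohort_bundle["cases"], cohort_bundle["pool"], ratio=4, rng_seed=11
        )
        pd.testing.assert_frame_equal(again.members, cohort_bundle["cohort"].members)

    def test_zero_cases_gives_empty_cohort(self, cohort_bundle):
        cases = cohort_bundle["cases"].iloc[0:0]
        cohort = match_controls(cases, cohort_bundle["pool"], ratio=4, rng_seed=0)
        assert cohort.members.empty

    def _tiny(self):
        cases = pd.DataFrame(
            {
                "person_id": ["C1", "C2"],
                "index_date": pd.to_datetime(["2004-06-01", "2005-06-01"]),
                "sex": ["female", "male"],
                "birth_date": pd.to_datetime(["1980-06-10", "1970-01-15"]),
            }
        )
        pool_rows = []
        for i in range(4):  # exactly 4 eligible per case (same sex, same age)
            pool_rows.append(("F%d" % i, "female", "1980-08-01"))
            pool_rows.append(("M%d" % i, "male", "1970-03-01"))
        pool = pd.DataFrame(pool_rows, columns=["person_id", "sex", "birth_date"])
        pool["birth_date"] = pd.to_datetime(pool["birth_date"])
        return cases, pool

    def test_unique_eligible_set_is_seed_invariant(self):
        cases, pool = self._tiny()
        a = match_controls(cases, pool, ratio=4, rng_seed=0)
        b = match_controls(cases, pool, ratio=4, rng_seed=999)
        pd.testing.assert_frame_equal(a.members, b.members)

    def test_insufficient_pool_raises(self):
        cases, pool = self._tiny()
        with pytest.raises(MatchingError, match="eligible"):
            match_controls(cases, pool.iloc[:5], ratio=4, rng_seed=0)

    def test_age_band_relaxation(self):
        cases, pool = self._tiny()
        # shift female pool one year younger: exact-age match now impossible
        pool = pool.copy()
        mask = pool["sex"] == "female"
        pool.loc[mask, "birth_date"] = pool.loc[mask, "birth_date"] + pd.DateOffset(years=1)
        with pytest.raises(MatchingError):
            match_controls(cases, pool, ratio=4, rng_seed=0)
        cohort = match_controls(
            cases, pool, ratio=4, rng_seed=0, age_band=1, on_insufficient="relax"
        )
        assert len(cohort.controls) == 8


class TestTransactions:
    def test_case_items_include_index_and_window_categories(self, cmap):
        cases = pd.DataFrame(
            {
                "person_id": ["C1"],
                "group": ["case"],
                "matched_case_id": [""],
                "sex": ["female"],
                "age": [25],
                "index_date": pd.to_datetime(["2004-06-01"]),
            }
        )
        from comorbidarm.cohort import Cohort

        cohort = Cohort(members=cases, match_ratio=4, seed=0)
        diag = _diag(
            [
                ("C1", "301.83", "2004-06-01"),
                ("C1", "296.40", "2005-01-01"),  # bipolar, inside window
                ("C1", "300.00", "2003-09-01"),  # anxiety, inside window
                ("C1", "486", "2000-01-01"),  # respiratory, outside window
            ]
        )
        trans = build_transactions(cohort, diag, cmap, window_years=3)
        assert trans["items"].iloc[0] == frozenset(
            {"BPD", "Bipolar disorder", "Anxiety disorder"}
        )

    def test_control_without_diagnoses_has_empty_transaction(self, cmap):
        from comorbidarm.cohort import Cohort

        members = pd.DataFrame(
            {
                "person_id": ["K1"],
                "group": ["control"],
                "matched_case_id": ["C9"],
                "sex": ["male"],
                "age": [30],
                "index_date": pd.to_datetime(["2004-06-01"]),
            }
        )
        cohort = Cohort(members=members, match_ratio=4, seed=0)
        trans = build_transactions(cohort, _diag([]), cmap, window_years=3)
        assert trans["items"].iloc[0] == frozenset()

    def test_counts_match_per_member_recount(self, cohort_bundle, transactions, cmap):
        """Aggregate per-category counts equal a direct member-by-member
        recount from the raw diagnosis records."""
        diagnoses = cohort_bundle["diagnoses"]
        members = cohort_bundle["cohort"].members
        rng = np.random.default_rng(0)
        sample = rng.choice(len(members), size=60, replace=False)
        lookup = dict(zip(transactions["person_id"], transactions["items"]))
        for i in sample:
            m = members.iloc[i]
            own = diagnoses[diagnoses["person_id"] == m["person_id"]]
            expected = person_category_set(own, m["index_date"], 3, cmap)
            expected.discard(cmap.index_label)
            if m["group"] == "case":
                expected.add(cmap.index_label)
            assert lookup[m["person_id"]] == frozenset(expected)

    def test_ordered_by_person_id(self, transactions):
        assert list(transactions["person_id"]) == sorted(transactions["person_id"])
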