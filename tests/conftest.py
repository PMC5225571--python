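from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from comorbidarm.cohort import build_transactions, match_controls, select_cases
from comorbidarm.icd_categories import default_category_map
from comorbidarm.synthetic_claims import SimulationConfig, generate_population


#: Narrower age anchors for small test populations, so exact age matching
#: always finds 4 controls per case at n of a few thousand.
NARROW_AGES = ((0.0, 20.0), (0.5, 27.0), (1.0, 40.0))


@pytest.fixture(scope="session")
def cmap():
    return default_category_map()


@pytest.fixture(scope="session")
def population(cmap):
    """Default-scenario synthetic population shared across tests."""
    cfg = SimulationConfig(n_persons=20_000, seed=7)
    persons, diagnoses = generate_population(cfg, cmap)
    return cfg, persons, diagnoses


@pytest.fixture(scope="session")
def cohort_bundle(population, cmap):
    """Matched cohort built from the shared population."""
    cfg, persons, diagnoses = population
    cases = select_cases(diagnoses, cfg.observation_window, cmap.index_code)
    cases = cases.merge(persons, on="person_id", how="inner")
    carriers = set(
        diagnoses.loc[diagnoses["icd9_code"] == cmap.index_code, "person_id"]
    )
    pool = persons[~persons["person_id"].isin(carriers)].reset_index(drop=True)
    cohort = match_controls(cases, pool, ratio=4, rng_seed=11)
    return {
        "config": cfg,
        "persons": persons,
        "diagnoses": diagnoses,
        "cases": cases,
        "pool": pool,
        "cohort": cohort,
    }


@pytest.fixture(scope="session")
def transactions(cohort_bundle, cmap):
    """Full-label transactions for the shared cohort."""
    return build_transactions(
        cohort_bundle["cohort"], cohort_bundle["diagnoses"], cmap, window_years=3
    )


@pytest.fixture(scope="session")
def arm_transactions(transactions, cmap):
    keep = frozenset(cmap.arm_items) | {cmap.index_label}
    out = transactions.copy()
    out["items"] = [s & keep for s in out["items"]]
    return out


def make_members(n_cases: int, n_controls: int) -> pd.DataFrame:
    """Minimal members table with only person_id/group (for split tests)."""
    rows = [
        {"person_id": f"C{i:05d}", "group": "case"} for i in range(n_cases)
    ] + [
        {"person_id": f"K{i:05d}", "group": "control"} for i in range(n_controls)
    ]
    return pd.DataFrame(rows)


def make_rule_transactions(
    n_cases: int,
    n_controls: int,
    case_with: int,
    control_with: int,
    consequent=("Anxiety disorder", "Bipolar disorder"),
    index_item: str = "BPD",
) -> pd.DataFrame:
    """Transactions with exact counts of consequent carriers per group."""
    y = frozenset(consequent)
    rows = []
    for i in range(n_cases):
        items = frozenset({index_item}) | (y if i < case_with else frozenset())
        rows.append({"person_id": f"C{i:05d}", "group": "case", "items": items})
    for i in range(n_controls):
        items = y if i < control_with else frozenset()
        rows.append({"person_id": f"K{i:05d}", "group": "control", "items": items})
    return pd.DataFrame(rows)
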