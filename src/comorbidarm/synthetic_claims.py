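"""Synthetic claims-like population generator.

The source registry for the motivating study (a national insurance claims
database) is access-restricted, so every downstream stage of this package is
exercised on populations generated here with *known* statistical structure:

* demographics — configurable female fraction and an age distribution given
  as piecewise-linear quantile anchors (defaults target median 25 years,
  interquartile range 21-33, roughly 65% female);
* an index disorder (borderline personality disorder, ICD-9-CM 301.83)
  carried with a configurable prevalence, coded on an enrollment ("index")
  date drawn uniformly from the observation window;
* comorbidity categories sampled per person from a logistic model whose
  case-status coefficient is ``log(target OR)``, so the population-level
  case-vs-non-case odds ratio of each category is the configured target;
  optional pairwise log-odds couplings induce extra dependence between
  categories (sampled sequentially in configuration order);
* each category membership is materialised as one concrete ICD-9-CM code
  drawn from the category's representative code list, dated uniformly
  within +/-3 years of the person's index (or pseudo-index) date.

Default category prevalences (baseline, among non-cases) and target odds
ratios emulate the magnitudes reported for claims-based borderline
personality disorder cohorts: very large ORs for mood disorders against
low baseline rates, moderate ORs for common physical categories.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .icd_categories import (
    ICD9_CODE_RE,
    CategoryMap,
    default_category_map,
)

__all__ = [
    "SimulationConfig",
    "ClaimsFormatError",
    "generate_population",
    "write_claims",
    "read_claims",
    "DEFAULT_CATEGORY_PREVALENCES",
    "DEFAULT_CATEGORY_ORS",
]

log = logging.getLogger(__name__)

#: Baseline (non-case) category prevalences for the default scenario.
DEFAULT_CATEGORY_PREVALENCES: dict[str, float] = {
    # physical chapters
    "Infectious and parasitic": 0.356,
    "Neoplasm": 0.115,
    "Endocrine, metabolic and immunity": 0.143,
    "Blood and blood-forming organs": 0.0479,
    "Nervous system and sense organs": 0.529,
    "Circulatory system": 0.111,
    "Respiratory system": 0.882,
    "Digestive system": 0.819,
    "Genitourinary system": 0.463,
    "Skin and subcutaneous tissue": 0.560,
    "Musculoskeletal system": 0.421,
    "Congenital anomalies": 0.0163,
    "Injury and poisoning": 0.532,
    # psychiatric leaves (substance subtypes, not their union)
    "Depressive disorder": 0.0205,
    "Bipolar disorder": 0.0223,
    "Anxiety disorder": 0.0634,
    "Sleep disorder": 0.0882,
    "Alcohol use disorder": 0.0026,
    "Opioid use disorder": 0.0010,
    "Amphetamine use disorder": 0.0010,
    "ADHD": 0.0020,
    "Mental retardation": 0.0026,
    "Autistic spectrum disorder": 0.0010,
    "Eating disorder": 0.0010,
}

#: Case-vs-non-case target odds ratios for the default scenario.
DEFAULT_CATEGORY_ORS: dict[str, float] = {
    "Infectious and parasitic": 1.71,
    "Neoplasm": 2.21,
    "Endocrine, metabolic and immunity": 2.07,
    "Blood and blood-forming organs": 2.97,
    "Nervous system and sense organs": 2.15,
    "Circulatory system": 3.01,
    "Respiratory system": 2.04,
    "Digestive system": 2.85,
    "Genitourinary system": 1.78,
    "Skin and subcutaneous tissue": 1.85,
    "Musculoskeletal system": 2.45,
    "Congenital anomalies": 2.14,
    "Injury and poisoning": 4.84,
    "Depressive disorder": 220.0,
    "Bipolar disorder": 261.0,
    "Anxiety disorder": 13.2,
    "Sleep disorder": 6.82,
    "Alcohol use disorder": 56.3,
    "Opioid use disorder": 21.0,
    "Amphetamine use disorder": 25.0,
    "ADHD": 8.7,
    "Mental retardation": 6.11,
    "Autistic spectrum disorder": 3.4,
    "Eating disorder": 24.0,
}

#: Quantile anchors (probability, age in years) targeting median 25,
#: IQR 21-33 and age-band shares ~12.7% / 77.4% / 9.9% for 0-19 / 20-39 /
#: 40-59.
DEFAULT_AGE_QUANTILES: tuple[tuple[float, float], ...] = (
    (0.0, 10.0),
    (0.127, 20.0),
    (0.25, 21.0),
    (0.50, 25.0),
    (0.75, 33.0),
    (0.901, 40.0),
    (1.0, 59.0),
)

COMORBIDITY_WINDOW_DAYS = 1095  # +/- 3 years around the (pseudo-)index date


@dataclass
class SimulationConfig:
    """Parameters of one synthetic population.

    The seed fully determines the output.  ``category_prevalences`` are
    baseline probabilities among non-cases; ``category_target_ors`` the
    case-vs-non-case odds ratios the population is constructed to exhibit.
    ``inter_category_dependence`` maps ordered category pairs ``(g, h)`` to a
    log-odds increment added to ``h`` when the person carries ``g`` (``h``
    must come after ``g`` in configuration order).
    """

    n_persons: int = 20_000
    female_fraction: float = 0.65
    age_quantiles: tuple[tuple[float, float], ...] = DEFAULT_AGE_QUANTILES
    index_disorder_prevalence: float = 0.02
    category_prevalences: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_PREVALENCES)
    )
    category_target_ors: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_ORS)
    )
    inter_category_dependence: dict[tuple[str, str], float] = field(
        default_factory=dict
    )
    observation_window: tuple[str, str] = ("2003-01-01", "2006-12-31")
    missing_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_persons <= 0:
            raise ValueError(f"n_persons must be positive, got {self.n_persons}")
        for label, p in [
            ("female_fraction", self.female_fraction),
            ("index_disorder_prevalence", self.index_disorder_prevalence),
        ]:
            if not 0.0 < p < 1.0:
                raise ValueError(f"{label} must lie in (0, 1), got {p}")
        if not 0.0 <= self.missing_fraction < 1.0:
            raise ValueError("missing_fraction must lie in [0, 1)")
        for g, p in self.category_prevalences.items():
            if not 0.0 < p < 1.0:
                raise ValueError(
                    f"category_prevalences[{g!r}] must lie in (0, 1), got {p}"
                )
            if g not in self.category_target_ors:
                raise ValueError(f"no target OR configured for category {g!r}")
        for g, r in self.category_target_ors.items():
            if r <= 0:
                raise ValueError(
                    f"category_target_ors[{g!r}] must be positive, got {r}"
                )
            if g not in self.category_prevalences:
                raise ValueError(f"no prevalence configured for category {g!r}")
            p1 = float(expit(logit(self.category_prevalences[g]) + np.log(r)))
            if not 0.0 < p1 < 1.0:
                raise ValueError(
                    f"unsatisfiable prevalence/OR combination for {g!r}: "
                    f"required case-conditional probability {p1} is degenerate"
                )
        order = list(self.category_prevalences)
        for (g, h) in self.inter_category_dependence:
            if g not in order or h not in order:
                raise ValueError(f"coupling ({g!r}, {h!r}) names unknown category")
            if order.index(g) >= order.index(h):
                raise ValueError(
                    f"coupling ({g!r}, {h!r}) must point forward in "
                    "configuration order"
                )
        start, end = (pd.Timestamp(d) for d in self.observation_window)
        if end < start:
            raise ValueError("observation_window end precedes start")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=int(seed))


def _sample_ages(rng: np.random.Generator, cfg: SimulationConfig) -> np.ndarray:
    q = np.array([p for p, _ in cfg.age_quantiles])
    v = np.array([a for _, a in cfg.age_quantiles])
    if not (np.all(np.diff(q) > 0) and q[0] == 0.0 and q[-1] == 1.0):
        raise ValueError("age_quantiles must be strictly increasing from 0 to 1")
    return np.interp(rng.random(cfg.n_persons), q, v)


def _sample_membership(
    rng: np.random.Generator, cfg: SimulationConfig, is_case: np.ndarray
) -> dict[str, np.ndarray]:
    """Sequential logistic sampling of per-person category membership."""
    member: dict[str, np.ndarray] = {}
    z = is_case.astype(float)
    for g, prev in cfg.category_prevalences.items():
        eta = logit(prev) + np.log(cfg.category_target_ors[g]) * z
        for (a, b), coupling in cfg.inter_category_dependence.items():
            if b == g:
                eta = eta + coupling * member[a].astype(float)
        member[g] = rng.random(cfg.n_persons) < expit(eta)
    return member


def generate_population(
    config: SimulationConfig, cmap: CategoryMap | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate one population of persons and dated diagnosis records.

    Returns
    -------
    persons : DataFrame
        Columns ``person_id``, ``sex``, ``birth_date``.
    diagnoses : DataFrame
        Columns ``person_id``, ``icd9_code``, ``diagnosis_date``; sorted by
        person, date, code.
    """
    config.validate()
    cmap = cmap or default_category_map()
    for g in config.category_prevalences:
        reps = cmap.representative_codes.get(g, ())
        if not reps:
            raise ValueError(
                f"category {g!r} has no representative codes in the map; "
                "cannot emit concrete diagnoses"
            )

    rng = np.random.default_rng(config.seed)
    n = config.n_persons
    person_id = np.array([f"P{i:07d}" for i in range(n)])
    sex = np.where(rng.random(n) < config.female_fraction, "female", "male")
    ages = _sample_ages(rng, config)

    start, end = (pd.Timestamp(d) for d in config.observation_window)
    span = (end - start).days
    index_date = start + pd.to_timedelta(rng.integers(0, span + 1, n), unit="D")
    birth_date = index_date - pd.to_timedelta(
        np.round(ages * 365.25).astype(int), unit="D"
    )

    is_case = rng.random(n) < config.index_disorder_prevalence
    member = _sample_membership(rng, config, is_case)

    pid_parts: list[np.ndarray] = []
    code_parts: list[np.ndarray] = []
    date_parts: list[pd.DatetimeIndex] = []

    case_idx = np.flatnonzero(is_case)
    pid_parts.append(person_id[case_idx])
    code_parts.append(np.full(case_idx.size, cmap.index_code, dtype=object))
    date_parts.append(pd.DatetimeIndex(index_date[case_idx]))

    w = COMORBIDITY_WINDOW_DAYS
    for g in config.category_prevalences:
        idx = np.flatnonzero(member[g])
        reps = np.asarray(cmap.representative_codes[g], dtype=object)
        codes = reps[rng.integers(0, reps.size, idx.size)]
        offsets = rng.integers(-w, w + 1, idx.size)
        pid_parts.append(person_id[idx])
        code_parts.append(codes)
        date_parts.append(
            pd.DatetimeIndex(index_date[idx]) + pd.to_timedelta(offsets, unit="D")
        )

    persons = pd.DataFrame(
        {"person_id": person_id, "sex": sex, "birth_date": birth_date}
    )
    if config.missing_fraction > 0:
        blank_sex = rng.random(n) < config.missing_fraction
        blank_bd = rng.random(n) < config.missing_fraction
        persons.loc[blank_sex, "sex"] = np.nan
        persons.loc[blank_bd, "birth_date"] = pd.NaT
        log.info(
            "blanked %d sex and %d birth_date fields completely at random",
            int(blank_sex.sum()),
            int(blank_bd.sum()),
        )

    diagnoses = pd.DataFrame(
        {
            "person_id": np.concatenate(pid_parts),
            "icd9_code": np.concatenate(code_parts),
            "diagnosis_date": pd.DatetimeIndex(np.concatenate(
                [d.values for d in date_parts]
            )),
        }
    )
    diagnoses = diagnoses.sort_values(
        ["person_id", "diagnosis_date", "icd9_code"], kind="mergesort"
    ).reset_index(drop=True)
    return persons, diagnoses


# ---------------------------------------------------------------------------
# Claims file I/O


class ClaimsFormatError(ValueError):
    """A claims file row failed validation; the message names line and field."""


PERSON_COLUMNS = ["person_id", "sex", "birth_date"]
DIAGNOSIS_COLUMNS = ["person_id", "sex", "birth_date", "icd9_code", "diagnosis_date"]


def write_claims(persons: pd.DataFrame, diagnoses: pd.DataFrame, path, fmt: str = "csv") -> None:
    """Write persons and diagnoses under directory ``path``.

    ``fmt`` is ``"csv"`` (``persons.csv`` / ``diagnoses.csv``, ISO-8601
    dates, diagnosis rows denormalised with the person's demographics) or
    ``"jsonl"``.
    """
    import pathlib

    path = pathlib.Path(path)
    path.mkdir(parents=True, exist_ok=True)
    diag_full = diagnoses.merge(persons, on="person_id", how="left")[DIAGNOSIS_COLUMNS]
    p = persons.copy()
    for df in (p, diag_full):
        for col in df.columns:
            if col.endswith("_date"):
                df[col] = pd.to_datetime(df[col]).dt.strftime("%Y-%m-%d")
    if fmt == "csv":
        p.to_csv(path / "persons.csv", index=False)
        diag_full.to_csv(path / "diagnoses.csv", index=False)
    elif fmt == "jsonl":
        for name, df in [("persons", p), ("diagnoses", diag_full)]:
            with open(path / f"{name}.jsonl", "w", encoding="utf-8") as fh:
                for rec in df.to_dict(orient="records"):
                    clean = {k: (None if pd.isna(v) else v) for k, v in rec.items()}
                    fh.write(json.dumps(clean) + "\n")
    else:
        raise ValueError(f"unknown claims format {fmt!r}")


def _validate_and_parse(df: pd.DataFrame, columns: list[str], name: str) -> pd.DataFrame:
    missing_cols = [c for c in columns if c not in df.columns]
    if missing_cols:
        raise ClaimsFormatError(f"{name}: missing columns {missing_cols}")
    df = df[columns].copy()
    for col in columns:
        if col.endswith("_date"):
            raw = df[col]
            parsed = pd.to_datetime(raw, format="%Y-%m-%d", errors="coerce")
            bad = parsed.isna() & raw.notna() & (raw.astype(str).str.len() > 0)
            if bad.any():
                i = int(np.flatnonzero(bad.to_numpy())[0])
                raise ClaimsFormatError(
                    f"{name} line {i + 2}: field {col!r} has "
                    f"unparseable date {raw.iloc[i]!r}"
                )
            df[col] = parsed
    if "sex" in columns:
        ok = df["sex"].isna() | df["sex"].isin(["female", "male"])
        if not ok.all():
            i = int(np.flatnonzero(~ok.to_numpy())[0])
            raise ClaimsFormatError(
                f"{name} line {i + 2}: field 'sex' has invalid value "
                f"{df['sex'].iloc[i]!r}"
            )
    if "icd9_code" in columns:
        codes = df["icd9_code"].astype(str)
        ok = codes.str.match(ICD9_CODE_RE)
        if not ok.all():
            i = int(np.flatnonzero(~ok.to_numpy())[0])
            raise ClaimsFormatError(
                f"{name} line {i + 2}: field 'icd9_code' has malformed code "
                f"{df['icd9_code'].iloc[i]!r}"
            )
        df["icd9_code"] = codes
    return df


def read_claims(path, fmt: str = "csv") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a claims directory written by :func:`write_claims`.

    Returns ``(persons, diagnoses)`` with the same schema as
    :func:`generate_population`; malformed rows raise
    :class:`ClaimsFormatError` naming the line number and field.
    """
    import pathlib

    path = pathlib.Path(path)
    if fmt == "csv":
        p_raw = pd.read_csv(path / "persons.csv", dtype={"person_id": str, "sex": str})
        d_raw = pd.read_csv(
            path / "diagnoses.csv", dtype={"person_id": str, "sex": str, "icd9_code": str}
        )
    elif fmt == "jsonl":
        def _read(name):
            rows = []
            with open(path / f"{name}.jsonl", "r", encoding="utf-8") as fh:
                for i, line in enumerate(fh):
                    line = line.strip()
                    if not line:
                        continue
                    try:
                        rows.append(json.loads(line))
                    except json.JSONDecodeError as exc:
                        raise ClaimsFormatError(
                            f"{name}.jsonl line {i + 1}: invalid JSON ({exc})"
                        ) from exc
            return pd.DataFrame(rows)

        p_raw, d_raw = _read("persons"), _read("diagnoses")
        if p_raw.empty:
            p_raw = pd.DataFrame(columns=PERSON_COLUMNS)
        if d_raw.empty:
            d_raw = pd.DataFrame(columns=DIAGNOSIS_COLUMNS)
    else:
        raise ValueError(f"unknown claims format {fmt!r}")

    persons = _validate_and_parse(p_raw, PERSON_COLUMNS, "persons")
    diag = _validate_and_parse(d_raw, DIAGNOSIS_COLUMNS, "diagnoses")
    diagnoses = diag[["person_id", "icd9_code", "diagnosis_date"]].reset_index(drop=True)
    return persons.reset_index(drop=True), diagnoses
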