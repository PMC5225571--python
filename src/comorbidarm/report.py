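"""End-to-end pipeline: synthetic claims (or claims files) in, six report
tables out.

The bundle mirrors a standard case-control comorbidity report:

* ``table1_demographics`` — case/control demographic balance with P values;
* ``table2_physical_or`` — per physical category, the within-case
  female-vs-male odds ratio and the case-vs-control odds ratio;
* ``table3_psychiatric_or`` — the same for psychiatric categories;
* ``table4_rules_train`` — lift-ranked rules mined on the training
  partition with per-rule case-control ORs;
* ``table5_rules_test`` — the same rules re-evaluated on the held-out
  partition;
* ``table6_bootstrap`` — matched-bootstrap means and percentile CIs.

Every stochastic stage consumes an explicit seed recorded in the metadata
sidecar, so a rerun of the same configuration reproduces the bundle
byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import __version__
from .arm import MiningConfig, TransactionSet, mine_rules
from .bootstrap import BootstrapConfig, bootstrap_rules, summaries_to_frame
from .cohort import (
    Cohort,
    build_transactions,
    filter_complete_cases,
    match_controls,
    select_cases,
)
from .contingency_stats import (
    compare_demographics,
    format_or,
    median_iqr,
    odds_ratio,
    two_by_two,
)
from .icd_categories import CategoryMap, default_category_map, load_category_map
from .synthetic_claims import SimulationConfig, generate_population, read_claims
from .validation import SplitSpec, evaluate_rule, split_cohort

__all__ = ["RunConfig", "run_pipeline"]

PSYCHIATRIC_DISPLAY = (
    "Depressive disorder",
    "Bipolar disorder",
    "Anxiety disorder",
    "Sleep disorder",
    "Substance use disorder",
    "Alcohol use disorder",
    "Opioid use disorder",
    "Amphetamine use disorder",
    "ADHD",
    "Mental retardation",
    "Autistic spectrum disorder",
    "Eating disorder",
)


@dataclass
class RunConfig:
    """Full pipeline configuration.

    ``seed`` is the master seed; the per-stage seeds (generation, matching,
    split, bootstrap) default to fixed offsets from it and are all recorded
    in the output metadata.
    """

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    claims_dir: str | None = None  # read claims instead of simulating
    claims_fmt: str = "csv"
    category_map_path: str | None = None
    enrollment_window: tuple[str, str] | None = None  # default: sim window
    ratio: int = 4
    window_years: float = 3
    mining: MiningConfig = field(default_factory=MiningConfig)
    split: SplitSpec = field(default_factory=SplitSpec)
    bootstrap: BootstrapConfig = field(default_factory=BootstrapConfig)
    seed: int = 0
    outdir: str | None = None

    @property
    def generation_seed(self) -> int:
        return self.seed

    @property
    def matching_seed(self) -> int:
        return self.seed + 1

    @property
    def split_seed(self) -> int:
        return self.seed + 2

    @property
    def bootstrap_seed(self) -> int:
        return self.seed + 3

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "sim" in kwargs:
            sim = dict(kwargs["sim"])
            if "observation_window" in sim:
                sim["observation_window"] = tuple(sim["observation_window"])
            if "inter_category_dependence" in sim:
                sim["inter_category_dependence"] = {
                    tuple(k.split("|")): v
                    for k, v in sim["inter_category_dependence"].items()
                }
            kwargs["sim"] = SimulationConfig(**sim)
        if "mining" in kwargs:
            m = dict(kwargs["mining"])
            if "antecedent_constraint" in m and m["antecedent_constraint"] is not None:
                m["antecedent_constraint"] = frozenset(m["antecedent_constraint"])
            if "consequent_sizes" in m:
                m["consequent_sizes"] = frozenset(m["consequent_sizes"])
            kwargs["mining"] = MiningConfig(**m)
        if "split" in kwargs:
            kwargs["split"] = SplitSpec(**kwargs["split"])
        if "bootstrap" in kwargs:
            kwargs["bootstrap"] = BootstrapConfig(**kwargs["bootstrap"])
        if "enrollment_window" in kwargs and kwargs["enrollment_window"] is not None:
            kwargs["enrollment_window"] = tuple(kwargs["enrollment_window"])
        return cls(**kwargs)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def _table1(cohort: Cohort) -> pd.DataFrame:
    m = cohort.members
    pvals = compare_demographics(m)
    cases = m[m["group"] == "case"]
    ctrls = m[m["group"] == "control"]
    rows = []

    def pct(x, n):
        return round(100 * x / n, 1) if n else float("nan")

    for sex in ("male", "female"):
        rows.append(
            {
                "variable": "sex",
                "level": sex,
                "case_n": int((cases["sex"] == sex).sum()),
                "case_pct": pct(int((cases["sex"] == sex).sum()), len(cases)),
                "control_n": int((ctrls["sex"] == sex).sum()),
                "control_pct": pct(int((ctrls["sex"] == sex).sum()), len(ctrls)),
                "p_value": pvals["sex_p"],
            }
        )
    cm, c1, c3 = median_iqr(cases["age"])
    km, k1, k3 = median_iqr(ctrls["age"])
    rows.append(
        {
            "variable": "age_median_iqr",
            "level": f"{cm:g} ({c1:g}-{c3:g}) vs {km:g} ({k1:g}-{k3:g})",
            "case_n": len(cases),
            "case_pct": float("nan"),
            "control_n": len(ctrls),
            "control_pct": float("nan"),
            "p_value": pvals["age_t_p"],
        }
    )
    for lo, hi in ((0, 19), (20, 39), (40, 59), (60, 200)):
        in_case = ((cases["age"] >= lo) & (cases["age"] <= hi)).sum()
        in_ctrl = ((ctrls["age"] >= lo) & (ctrls["age"] <= hi)).sum()
        if in_case == 0 and in_ctrl == 0:
            continue
        rows.append(
            {
                "variable": "age_band",
                "level": f"{lo}-{hi}",
                "case_n": int(in_case),
                "case_pct": pct(int(in_case), len(cases)),
                "control_n": int(in_ctrl),
                "control_pct": pct(int(in_ctrl), len(ctrls)),
                "p_value": pvals["age_band_p"],
            }
        )
    return pd.DataFrame(rows)


def _category_table(
    trans: pd.DataFrame, members: pd.DataFrame, categories, level: float = 0.95
) -> pd.DataFrame:
    """Within-case female-vs-male and case-vs-control OR rows per category."""
    merged = trans.merge(
        members[["person_id", "sex"]], on="person_id", how="left"
    )
    cases = merged[merged["group"] == "case"]
    rows = []
    for cat in categories:
        rec: dict = {"category": cat}
        # female vs male within cases
        both_sexes = cases["sex"].nunique() == 2
        if both_sexes:
            t_fm = two_by_two(cases, cat, group_col="sex", groups=("female", "male"))
            est_fm = odds_ratio(t_fm, level=level)
            nf = int((cases["sex"] == "female").sum())
            nm = int((cases["sex"] == "male").sum())
            rec.update(
                female_pct=round(100 * t_fm.a / nf, 1) if nf else float("nan"),
                male_pct=round(100 * t_fm.b / nm, 1) if nm else float("nan"),
                or_fm=est_fm.or_value,
                or_fm_ci_low=est_fm.ci_low,
                or_fm_ci_high=est_fm.ci_high,
                or_fm_significant=est_fm.significant,
                or_fm_display=format_or(est_fm.or_value),
            )
        t_cc = two_by_two(merged, cat)
        est = odds_ratio(t_cc, level=level)
        n_case = int((merged["group"] == "case").sum())
        n_ctrl = int((merged["group"] == "control").sum())
        rec.update(
            a=t_cc.a,
            b=t_cc.b,
            case_pct=round(100 * t_cc.a / n_case, 1),
            control_pct=round(100 * t_cc.b / n_ctrl, 2),
            odds_ratio=est.or_value,
            ci_low=est.ci_low,
            ci_high=est.ci_high,
            significant=est.significant,
            or_display=format_or(est.or_value),
        )
        rows.append(rec)
    return pd.DataFrame(rows)


def _rule_table(rules, trans: pd.DataFrame, index_item: str) -> pd.DataFrame:
    rows = []
    for rule in rules:
        ev = evaluate_rule(rule, trans, index_item=index_item)
        rows.append(
            {
                "relations": rule.relations,
                "support": ev.support,
                "confidence": ev.confidence,
                "lift": ev.lift,
                "rule": rule.label,
                "n_cases": ev.n_cases_with,
                "n_controls": ev.n_controls_with,
                "odds_ratio": ev.or_estimate.or_value,
                "ci_low": ev.or_estimate.ci_low,
                "ci_high": ev.or_estimate.ci_high,
                "significant": ev.or_estimate.significant,
                "or_display": format_or(ev.or_estimate.or_value),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "relations", "support", "confidence", "lift", "rule",
            "n_cases", "n_controls", "odds_ratio", "ci_low", "ci_high",
            "significant", "or_display",
        ],
    )


def _restrict_items(trans: pd.DataFrame, keep: frozenset) -> pd.DataFrame:
    out = trans.copy()
    out["items"] = [s & keep for s in out["items"]]
    return out


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full analysis and return the report bundle.

    The bundle maps table names to DataFrames plus a ``metadata`` dict; when
    ``cfg.outdir`` is set, tables are written as CSV with a JSON metadata
    sidecar.
    """
    cmap: CategoryMap = (
        load_category_map(cfg.category_map_path)
        if cfg.category_map_path
        else default_category_map()
    )

    if cfg.claims_dir:
        persons, diagnoses = _stage("read_claims")(read_claims)(
            cfg.claims_dir, fmt=cfg.claims_fmt
        )
    else:
        persons, diagnoses = _stage("generate")(generate_population)(
            cfg.sim.with_seed(cfg.generation_seed), cmap
        )

    n_before = len(persons)
    persons_cc = _stage("complete_case")(filter_complete_cases)(persons)
    n_dropped = n_before - len(persons_cc)

    window = cfg.enrollment_window or cfg.sim.observation_window
    cases = _stage("select_cases")(select_cases)(diagnoses, window, cmap.index_code)
    cases = cases.merge(persons_cc, on="person_id", how="inner")

    carrier_ids = set(diagnoses.loc[diagnoses["icd9_code"] == cmap.index_code, "person_id"])
    pool = persons_cc[~persons_cc["person_id"].isin(carrier_ids)]

    cohort = _stage("match_controls")(match_controls)(
        cases, pool, ratio=cfg.ratio, rng_seed=cfg.matching_seed
    )

    trans_all = _stage("build_transactions")(build_transactions)(
        cohort, diagnoses, cmap, window_years=cfg.window_years, items=None
    )

    table1 = _table1(cohort)
    table2 = _category_table(trans_all, cohort.members, cmap.physical_names)
    psych = [c for c in PSYCHIATRIC_DISPLAY if c in cmap.psychiatric_names]
    table3 = _category_table(trans_all, cohort.members, psych)

    arm_universe = tuple(cmap.arm_items) + (cmap.index_label,)
    trans_arm = _restrict_items(trans_all, frozenset(arm_universe))

    train, test = _stage("split")(split_cohort)(
        trans_arm, SplitSpec(cfg.split.train_fraction, cfg.split_seed)
    )
    mining = dataclasses.replace(
        cfg.mining, antecedent_constraint=frozenset({cmap.index_label})
    )
    ts_train = TransactionSet.from_frame(train, universe=sorted(arm_universe))
    rules = _stage("mine")(mine_rules)(ts_train, mining)

    table4 = _rule_table(rules, train, cmap.index_label)
    table5 = _rule_table(rules, test, cmap.index_label)

    if rules:
        boot_cfg = dataclasses.replace(
            cfg.bootstrap,
            seed=cfg.bootstrap_seed,
            ratio=cfg.ratio,
            window_years=cfg.window_years,
        )
        summaries = _stage("bootstrap")(bootstrap_rules)(
            cases, pool, diagnoses, rules, cmap, boot_cfg
        )
        table6 = summaries_to_frame(summaries)
    else:
        table6 = summaries_to_frame([])

    metadata = {
        "package_version": __version__,
        "seeds": {
            "master": cfg.seed,
            "generation": cfg.generation_seed,
            "matching": cfg.matching_seed,
            "split": cfg.split_seed,
            "bootstrap": cfg.bootstrap_seed,
        },
        "n_persons": int(n_before),
        "n_dropped_complete_case": int(n_dropped),
        "n_cases": int(len(cohort.cases)),
        "n_controls": int(len(cohort.controls)),
        "match_ratio": cfg.ratio,
        "window_years": cfg.window_years,
        "train_fraction": cfg.split.train_fraction,
        "bootstrap_B": cfg.bootstrap.B,
        "n_rules": len(rules),
        "ci_method": "percentile",
        "source": "claims_dir" if cfg.claims_dir else "synthetic",
    }

    bundle = {
        "table1_demographics": table1,
        "table2_physical_or": table2,
        "table3_psychiatric_or": table3,
        "table4_rules_train": table4,
        "table5_rules_test": table5,
        "table6_bootstrap": table6,
        "metadata": metadata,
        "cohort": cohort,
        "transactions": trans_arm,
    }

    if cfg.outdir:
        outdir = pathlib.Path(cfg.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, obj in bundle.items():
            if isinstance(obj, pd.DataFrame) and name.startswith("table"):
                obj.to_csv(outdir / f"{name}.csv", index=False)
        with open(outdir / "metadata.json", "w", encoding="utf-8") as fh:
            json.dump(metadata, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return bundle
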