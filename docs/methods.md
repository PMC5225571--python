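# Methods

This note documents the statistical model behind `comorbidarm`, the
conventions and numerical choices baked into each stage, what the synthetic
data generator does and does not emulate, and the known limitations.

## Study design

The package implements a retrospective matched case–control design on
claims-like records. A *case* is a person whose **first** occurrence of the
index code (borderline personality disorder, ICD-9-CM 301.83) falls inside
an enrollment window; any earlier occurrence disqualifies the person
(incidence requirement). For each case, `ratio` (default 4) controls are
drawn uniformly at random, without replacement across the cohort, from
non-carriers with **identical sex and identical completed age in years** at
the case's index date. Exact matching means the control sex/age marginals
equal the case marginals by construction, so demographic-balance tests
(chi-squared for sex and banded age, two-sample t for age) return P ≈ 1 on
every matched cohort — this is a design property, not a finding.

Controls inherit the matched case's index date, which anchors their
comorbidity window; this is the standard matched-design convention when a
control has no natural enrollment date of its own. A ± band fallback for
age exists (`age_band`, logged per use) but is off by default; persons with
any missing demographic field are dropped beforehand (complete-case
analysis, assuming missingness completely at random), with the dropped
count recorded in run metadata.

## Category coding

Physical comorbidities are the 13 ICD-9-CM chapter ranges over the 3-digit
code root (infectious 001–139 through injury and poisoning 800–999).
Psychiatric categories are explicit dotted-prefix sets; the shipped defaults
use conventional groupings (e.g. depressive = 296.2x/296.3x/300.4/311,
bipolar = 296.0x–296.1x/296.4x–296.8x, substance use = union of the
alcohol/opioid/amphetamine subtype sets). These groupings are a
configuration choice, not a canonical fact, and can be replaced wholesale
from a YAML file. V- and E-prefixed codes fall outside the numeric grammar
and map to no category (with a warning). A code may carry one physical and
one or more psychiatric labels simultaneously (the 327 organic-sleep block
sits inside the nervous-system chapter).

The comorbidity window is **closed**: a diagnosis exactly `w` years from
the index date counts. Integer windows use calendar arithmetic (same
month/day `w` years away), so leap days cannot silently exclude a boundary
diagnosis; fractional windows fall back to `365.25·w` days.

## Odds ratios

All ORs are unconditional cross-product ratios `(a·d)/(b·c)` with Wald
intervals on the log scale at `z = 1.959964`. For a single binary exposure
this is numerically identical to the exponentiated coefficient of a
univariable logistic regression (verified in tests against an independent
GLM fit to 1e-6), which is how such tables are conventionally produced.
Matched-pair (conditional) estimation is deliberately **not** used — the
design estimates the same unconditional quantity the reference tables
print. Tables with any zero cell are reported as undefined and rendered
`--`; the Haldane–Anscombe +0.5 correction is available by flag and keeps
every table with positive margins finite. Report rendering uses 3
significant figures, with ORs ≥ 100 shown as integers.

## Rule mining

Each cohort member contributes one transaction: the index item (cases
only) plus the member's psychiatric category set inside the window. Support
is computed over the **full** transaction set (cases + controls), so for an
antecedent fixed to the index item, confidence is the comorbidity rate
among cases and lift compares it with the overall consequent rate in the
matched cohort.

Mining runs in the lift-only regime: minsup and minconf are conceptually 0,
rules require lift strictly greater than 1, and the top-*k* (default
10,000) by lift are kept. Zero-support mining is exponential in the item
universe, so level-wise enumeration is bounded by a maximum rule size
(antecedent + consequent, default 4, matching the largest reported
"relations" value) and a hard itemset budget; the intended universe is a
dozen curated categories, and the miner refuses larger universes rather
than silently truncating. Transactions are bitmask-encoded (≤ 64 items).
Ties in lift are broken by support, then confidence, then the
lexicographic rule label, making output order deterministic. On universes
small enough to enumerate, the miner's output (rule identity, order and all
metrics) is tested to equal a plain exhaustive enumeration over all
disjoint (X, Y) pairs.

## Train/test validation

The split is a person-level stratified random partition: within each group
(case, control) a fraction `round(f·n)` (default f = 2/3) goes to training,
preserving the 1:4 ratio in both partitions (292/1168 members split to
195/779 and 97/389). Rules mined on the training partition are re-evaluated
on the held-out partition; per-rule ORs tabulate carrying the **full
consequent set** (cases vs controls), which for index-antecedent rules
coincides with full-rule exposure among cases.

## Matched bootstrap

Each of B (default 1000) replicates draws the cases with replacement
(duplicates retained as distinct transactions), re-matches `ratio` exact
age/sex controls per drawn case, rebuilds transactions and re-evaluates the
fixed input rule set. Controls are drawn without replacement within one
case's draw but with replacement across case instances and replicates (the
pool is not depleted across replicates). Rule discovery itself is not
bootstrapped; the rules are fixed inputs.

Two intervals are reported per metric:

* the **percentile interval** of the replicate distribution — endpoints are
  the `⌈α/2·B⌉`-th and `⌈(1−α/2)·B⌉`-th order statistics (an explicit
  rounding guard keeps exact boundaries such as 0.025·1000 on the 25th
  order statistic). This describes replicate spread, drives the
  significance flags (interval excluding 1), and its width converges to the
  width of the sampling distribution as B grows;
* the **CI of the mean metric**, `mean ± z·sd/√B`, whose width shrinks as
  1/√B. Bootstrap-mean tables in the applied literature print intervals of
  this kind (their width is far too small to be percentile intervals of the
  replicate distribution), so both are exposed rather than forcing one
  interpretation.

Replicates in which a rule's OR is undefined (zero cell — typical when no
control carries a rare consequent) are excluded from the OR mean and
interval; the count of defined replicates is reported, and a rule with no
defined replicate renders `--`.

## Synthetic data generator

The generator emulates the observable structure of the motivating cohort,
not the registry's data-generating process (which is unpublished):

* **Demographics.** Sex ~ Bernoulli(0.65 female). Age is drawn from a
  piecewise-linear inverse CDF through quantile anchors; the defaults hit
  median 25, IQR 21–33 and age-band shares ≈ 12.7% / 77.4% / 9.9% for
  0–19 / 20–39 / 40–59. Case status is independent of age and sex, so
  cohort ORs estimate the population ORs without confounding.
* **Index disorder.** Carried with configurable prevalence (default 0.02 at
  n = 20,000, yielding a few hundred incident cases with an ample matched
  pool); coded once, on an index date uniform in the observation window
  (2003–2006 by default). Non-cases get a pseudo-index date the same way.
* **Comorbidities.** Each category is sampled per person from a logistic
  model: `logit P(g) = logit(prev_g) + log(OR_g)·case + couplings`, so the
  population case-vs-non-case odds ratio equals the target exactly (without
  couplings). Optional pairwise log-odds couplings are applied sequentially
  in configuration order (a simple auto-logistic scheme); defaults use
  none. Each membership is materialised as one concrete code drawn
  uniformly from the category's representative list, dated uniformly within
  ±3 years of the person's (pseudo-)index date. Default prevalences and
  target ORs reproduce the magnitudes typical of claims-based borderline
  personality disorder cohorts (e.g. depressive baseline 2.05% with target
  OR 220; respiratory baseline 88.2% with target OR 2.04); where a
  reference control rate is zero, a small positive baseline (0.1–0.2%) with
  a case-rate-consistent OR is used instead, since a zero baseline admits
  no finite OR target.
* **Missingness.** An optional fraction of demographic fields is blanked
  completely at random (default 0) to exercise complete-case filtering.

A single integer seed fully determines the output; identical configurations
produce byte-identical record files.

**What the generator does not emulate** — visit-level utilisation,
reimbursement, prescriptions, code-level (rather than category-level)
structure, secular trends, and age/sex-dependent comorbidity risk. Passing
tests therefore demonstrate the *pipeline's* correctness against known
parameters, not fidelity of any particular registry.

One interaction worth knowing: a control's generated comorbidity dates
cluster around its **own** pseudo-index date, while the cohort anchors its
window at the matched case's index date. With a 3-year window and a 4-year
enrollment span this censors part of the control's record and deflates
control prevalences in cohort tables relative to the generator baselines
(inflating cohort ORs above their population targets). Validation tests
that compare against generator targets therefore either tabulate at each
person's own anchor or widen the window enough (≥ 7 years under the
defaults) that anchoring cannot censor a generated diagnosis. A narrow
(one-year) enrollment window makes the effect negligible.

## Problem sizes

Parameter-recovery checks run at n = 200,000 persons (three Monte-Carlo
standard errors on the log-OR scale for targets {1, 2, 6, 50}); the
end-to-end pipeline examples use n = 20,000 with B = 200 bootstrap
replicates; the bootstrap coverage study uses 50 independent experiments of
n = 6,000 with B = 200, checking that the percentile OR interval covers a
known target of 6 in ≥ 90% of experiments. These sizes were chosen so each
check is decisively powered while the whole suite stays comfortably
runnable on a laptop.

## Limitations

* Exact integer-age matching can fail in small populations at the edges of
  the age distribution (a case at the distribution's minimum age with a
  late index date has few same-age pool members); the matcher fails loudly
  with the offending case rather than silently relaxing. Use the `age_band`
  fallback or a larger pool.
* Only univariable estimation is provided — no covariate adjustment,
  conditional logistic models, Fisher exact intervals, or
  incidence-density/propensity matching.
* The rule miner targets curated category universes; it is not an
  FP-growth-style engine for raw code vocabularies.
* Percentile and mean-CI bootstrap intervals are the only interval types;
  no BCa or studentised variants.
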