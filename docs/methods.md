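# Methods

## The analysis

Spinal muscular atrophy (SMA) is caused by loss of the ubiquitously
expressed SMN protein, yet it is studied almost exclusively as a motor
neuron disease. This package implements a claims-database strategy for
asking whether systemic, non-neuromuscular phenotypes are diagnosed at
elevated rates in SMA patients — and whether they appear *before* the first
clinical sign of neuromuscular degeneration, where they cannot be secondary
to muscle weakness. The pipeline has four stages.

**1. Cohort selection.** From longitudinal diagnosis-code data (members:
demographics and one continuous enrollment span; claims: dated ICD9 codes),
cases are members with SMA codes on at least two distinct service dates
("different visits"; the schema carries no visit identifier, so distinct
dates are the only available operationalization). Two exclusions guard
against false cases: members whose *latest* neuromuscular-coded date
carries a non-SMA neuromuscular diagnosis (muscular dystrophy, myoneural
disorders — likely SMA misdiagnoses) and members with any pregnancy-billing
code (prenatal SMA testing generates SMA codes on the mother's record).
A same-date tie on the final-diagnosis rule counts as SMA-final, because
SMA claims routinely co-occur with degeneration codes on a single encounter
and the rule targets *later* competing diagnoses. Cases stratify by age at
first SMA code into Group A [0, 2) years (infantile onset), Group B
[2, 21), and Group C [21, 65]. Controls are every member with zero SMA
codes whose age at enrollment start falls inside the group's case
enrollment-age range; pools of different groups may overlap. Everyone
needs ≥ 6 months of coverage inside the analysis window (months are fixed
at 30.4375 days throughout, so no result depends on calendar conventions).
Pregnancy codes do not exclude controls by default (they carry no SMA
codes); a flag extends the exclusion to controls for sensitivity analyses.

**2. Windows.** The *entire-coverage* analysis uses each member's full
enrollment. The *pre-degeneration* analysis ends the day before the
member's **inflection point** — the earliest claim bearing any
neuromuscular-disease or degeneration code. "Prior to" is read strictly:
the inflection date itself is excluded, since diagnoses on that encounter
are part of the degeneration presentation. Controls carrying neuromuscular
codes are truncated at their own inflection by default (`truncate_controls`),
so both arms are filtered symmetrically; the flag can disable this.
The 6-month minimum inside the pre window doubles as a washout against
SMA diagnoses that predate coverage; no additional washout is applied.

**3. Screening.** ICD9 codes aggregate to PheWAS groups (phecodes) through
a flat, user-supplied map — each ICD9 to exactly one group, unmapped codes
counted but not analyzed; no hierarchical rollup is attempted. Groups with
member-level prevalence ≥ 1% in *either* arm (inclusive) are tested with
maximum-likelihood logistic regression

    phenotype ~ sma + gender + age_at_enrollment + enrollment_months

where the outcome is "≥ 1 claim in the window mapping to the group",
gender is a female indicator (unknown gender dropped by default), age is
at enrollment start (day precision where a birth date exists, calendar-year
arithmetic otherwise — the mode used is recorded in output metadata), and
enrollment months count time inside the analysis window, not total
coverage. The adjusted odds ratio is exp(coef(sma)) with a Wald p-value
(the conventional choice for phenome-wide screens), and Benjamini–Hochberg
step-up adjustment is applied across all phenotypes tested within one
(group × window) run. Extreme imbalance is reported as-is with a
`separation_flagged` status (|log-OR| > 15 or a non-finite standard error);
a hand-written Firth-type penalized fit (Jeffreys-prior score correction
with step-halving Newton iterations) is available but off by default, so
the default output matches a plain glm()-style screen that prints
near-separated odds ratios rather than shrinking them.

**4. Trajectories.** For pre-degeneration runs only, phenotypes with
adjusted p < 0.05 (strict) pool by physiological system; each system is
re-fit with the same regression on the union outcome ("any phenotype of
the system"). Temporal ordering uses the median, over contributing cases,
of days from the first window claim of any ICD9 in the system to the
inflection point (negative = before; even counts take the midpoint
average). Systems with ≥ 5% case prevalence enter the visual timeline,
earliest first. As an artifact check, |offset| in days is regressed on
enrollment months in the window, pooled over (case, system) contributions
within a group: R² near zero says the ordering is not driven by how long
members happened to be enrolled. The pooling choice is surfaced in output
metadata because the diagnostic could plausibly be computed per system;
pooled-per-group is what the summary R² values refer to.

## The synthetic study

No real claims accompany the project (insurer databases are proprietary),
so every stage runs against a generator whose model matches the analysis
model, making parameter recovery a sharp test:

* Phenotype occurrence is Bernoulli with
  `logit = logit(baseline) + log(OR)·case + β_f·female + β_a·(age−ā) +
  β_m·(months−m̄)`. Covariate coefficients default to zero; setting them
  nonzero creates genuine confounding and tests the adjustment.
* Case-like members receive their first SMA code at the planted inflection
  date (plus a degeneration code the same day and further SMA codes at
  30-day spacing), so the pre window contains no neuromuscular codes —
  the structure the selection rules assume. Case phenotype onsets are
  `inflection + Normal(offset_mean, offset_sd)` days, truncated into the
  enrollment span; control onsets are uniform over enrollment.
* Contamination scenarios plant exactly the failure modes the exclusions
  target: pregnancy-billing pseudo-cases, members with a later non-SMA
  neuromuscular diagnosis, and single-SMA-code members.
* All randomness is counter-based (a splitmix64 finalizer over
  (seed, role, within-role index, draw tag)): identical configs produce
  byte-identical tables, and resizing one arm never reshuffles another.

Defaults, chosen once as plausible for a claims population and held fixed:
enrollment 24–72 months uniform; enrollment era starting 2008-01-01
(cosmetic); inflection delay 270–540 days after enrollment start, which
guarantees the 6-month pre window; gender balance 0.5; background
(unmapped routine-visit) claim rate 0 per month unless a scenario sets it.
Infeasible combinations (an inflection delay that cannot fit the
post-inflection code stream inside the shortest enrollment) fail fast.

What the generator deliberately does **not** emulate: realistic ICD9
marginal frequencies, billing/utilization bursts, enrollment gaps,
multiple codes per claim line, or diagnosis-intensity differences beyond
the planted effects. Passing tests therefore demonstrate that the pipeline
recovers truth when the data match its assumptions — not that those
assumptions hold in any real claims feed.

## Numerical choices and conventions

* ICD9 canonical form: dots removed, then whitespace stripped, uppercased;
  normalization is idempotent and all matching uses canonical forms.
* Months = days / 30.4375, years = days / 365.25; coverage and window-length
  boundaries are inclusive (an exactly-6.0-month window passes the gate,
  with a 1e-9-month epsilon guarding float division).
* The 1% prevalence filter and the 5% timeline cut are inclusive at the
  boundary (a 1e-12 epsilon guards representation error).
* Logistic fits: Newton, 200-iteration cap; constant covariate columns
  (other than the exposure) are dropped to keep the design full rank; a
  constant outcome is skipped with a diagnostic rather than an error.
* BH adjustment is delegated to statsmodels' step-up implementation; the
  test suite checks it against an independent brute-force of the step-up
  definition.
* Table-1-style arm comparisons: two-sided Welch t for continuous rows,
  two-proportion z for percent female (the tests are named in the output
  metadata since descriptive tables often leave them implicit).
* Manhattan export clamps p = 0 to the smallest positive double before
  −log10 and flags the clamp.

## Problem sizes

Simulated studies were sized to exercise every code path while keeping a
single-CPU run of the full suite in minutes: the bundled scenarios use
80–300 cases against 5,000–30,000 controls, 15–200 null phenotypes,
and 10% contamination per scenario; statistical checks use 10–50
replicates (OR recovery and CI calibration) and 20 replicates of 200
phenotypes (FDR under the global null). The analysis drivers under
`analysis/` print their findings and write compact summaries under
`results/`; bulky intermediate tables live under `scratch/`.

## Known limitations

* "Different visits" cannot be distinguished from same-day claims from two
  providers; distinct service dates are the best available proxy.
* How control data should be handled in the pre-degeneration window is
  genuinely underdetermined by the study design; truncation at the
  control's own inflection is the default because it treats both arms
  symmetrically, and the flag exists precisely because the alternative
  (leave controls untouched) is defensible.
* The R² artifact diagnostic is one of several constructions consistent
  with its verbal definition; the regressed quantity is stated in the
  output metadata.
* The bundled vocabulary is a compact stand-in: production analyses must
  supply the full phecode table and clinically curated SMA/neuromuscular/
  pregnancy code sets, which are not redistributed here.
* Wald p-values can be anticonservative for very rare outcomes near
  separation; such rows arrive flagged, and the Firth mode exists for
  sensitivity analysis.
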