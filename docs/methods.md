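# Methods

This note documents the models, conventions and design choices behind
the package, in the order the pipeline applies them.

## Cohort construction

**Index date.** The two-branch definition (registration date if an R03
dispensing occurred that day, else the last R03 dispensing before it)
collapses to a single rule: the latest R03 dispensing on or before the
registration date. `resolve_index_date` implements that rule; it returns
nothing when no R03 dispensing exists on or before registration, and
such patients are traced separately (between criteria 2 and 3) because
the source criteria do not name this case.

**Windows.** Both analysis windows are fixed at 365 days — before =
[index − 365, index − 1], after = [index, index + 364], closed — rather
than calendar years. Calendar years straddling February 29 would give
366-day denominators for some patients; a fixed 365-day window keeps the
PDC denominator uniform, at the cost of a one-day offset in leap years.
Window arithmetic is tested across leap-year boundaries.

**Eligibility.** The five criteria run in their stated order and each
exclusion is attributed to the first failing criterion, so the filter
trace partitions the input exactly. Two readings were open:

* Criterion 3 ("registration at most 30 days after the index date") is
  computed as `registration − index ≤ 30` days, inclusive.
* Criterion 5's "at least one medication dispensing record before … and
  after" counts *any* medication, not only R03, since its purpose is to
  establish that the patient's dispensing history is complete over the
  period.

**User types.** New users have zero R03 dispensings in the before-window.
Any R03 code counts by default (relievers included); a
`maintenance_set` argument restricts the rule to maintenance products
for sensitivity analyses. A dispensing exactly on the index date belongs
to the after-window, so a patient whose first-ever R03 dispensing is the
index dispensing is a new user.

**Age.** Only the birth year is available, so age at first dispensing is
`year(first dispensing) − birth_year`; this can overstate age by up to
one year. The ≥ 18 rule uses this convention.

**Index anchors for never-offered controls.** Patients never offered
the intervention have no real registration event. The pipeline requires
an anchor date for everyone; the synthetic data gives these patients a
registration-equivalent date at one of their dispensing visits, mirroring
how the offer itself is tied to a refill visit.

## Proportion of days covered

Coverage is day-level set semantics: each maintenance dispensing covers
the closed interval `[date, date + covering_days − 1]`; a window day is
covered when at least one product's interval contains it ("at least
one" method); covered days are the union of intervals intersected with
the window. Overlapping supplies of the same or different products
cannot extend coverage (no stockpiling), and the union automatically
implements both boundary rules: a record dated before the window
contributes its in-window residual days, and the last record's coverage
is truncated at the window end.

A PDC is *missing* when no record exists on or before the window end —
then nothing is known about the window at all. A patient whose records
all predate the window (coverage demonstrably exhausted) has PDC 0, not
missing. PDCs are reported on the 0–100 scale with denominator 365; the
0.8 good-adherence cutoff is applied as PDC ≥ 80; reported values are
rounded to 2 decimals and compared in tests at absolute tolerance 0.005.
The ≥ 3-dispensing rule counts maintenance R03 records (the adherence
measurement set) within the 2-year period.

Nebulizer products have no ATC-level marker in dispensing data; the
package uses an optional `product_form` column (values in
`nebulizer_forms`) and logs a no-op warning when the column is absent.

## Exacerbation proxy

One qualifying prednis(ol)one record = one exacerbation: dose exactly in
{30, 40} mg/day (taken from the prescribed-daily-dosage field, not
re-derived from pack strength) and covering days in [5, 14], both
bounds inclusive. Consecutive or overlapping courses are not merged —
no gap/merge rule is defined for this proxy — and a prednisone record
without a recorded daily dose is not counted (logged as a data-quality
warning).

## Antimycotic outcome

Inclusion (≥ 1 ICS dispensing) is assessed over the union of both
windows, which keeps the per-group denominator constant across the
before/after rows; the binary outcome itself is window-restricted.

## Statistics

* **t tests**: Student (pooled variance), df = n₁ + n₂ − 2, two-sided
  at α = .05, contrast oriented control − intervention. The pooled form
  (rather than Welch) matches the degrees of freedom convention of the
  summarized analyses.
* **Cohen d** = contrast / pooled SD of the analyzed scores (difference
  scores for pre-post outcomes, post-index PDC for new users). The
  formula is fixed here because conventions differ.
* **ANCOVA screen**: OLS of the difference score on group + age +
  gender (unknown gender excluded); a covariate with p ≤ .05 triggers
  stratified re-analysis (per gender level).
* **Demographics**: Pearson chi-square without continuity correction on
  the 2×2 male/female table — the unknown-gender row is reported
  descriptively but excluded from the test, as a three-level test with a
  near-empty cell is unstable — and a pooled t test for age.
* **GLMM**: random-intercept logistic regression fitted by maximum
  likelihood with 25-node Gauss–Hermite quadrature over the
  per-patient intercept, optimized by L-BFGS-B on (β, log σ) with
  analytic gradients; log σ is bounded in [−12, 3] so a zero-variance
  fit terminates cleanly at the boundary. Standard errors come from the
  inverse observed information; at the σ = 0 boundary only the
  fixed-effects block is inverted (the log-σ direction is flat). With
  σ fixed at 0 the fit reproduces ordinary logistic regression to
  < 1e-4 (tested), and estimates match an independent
  trapezoid-likelihood grid search and lme4-style adaptive quadrature
  to ~1e-4 on fixtures. Complete separation (|β| > 15) triggers an
  automatic rerun with a weak L2 penalty (1e-3), flagged on the result.
  Only a per-patient intercept is modelled; pharmacy-level clustering is
  out of scope. No multiplicity correction is applied anywhere.

## Synthetic data generator

The generator's purpose is to give every downstream stage data with the
statistical structure the analysis assumes, with known ground truth.

**Refill model.** Maintenance refills form a discrete renewal process:
a dispensing covers C days (C ∈ {30, 60, 90} with probabilities
0.5/0.3/0.2 — one-to-three-month supplies, short supplies most common),
then a gap G ~ Poisson(g·w) days elapse before the next refill. Refills
are never early and stock never accumulates, which is exactly the
coverage model the PDC estimator assumes. The patient-level frailty
multiplier w (discrete grid 0.3/0.7/1.0/1.6/3.0 with probabilities
0.15/0.25/0.30/0.20/0.10) makes some patients near-perfect refillers
and gives a long-gap tail; it is drawn once per patient and shared
across periods, so adherence levels persist over time.

**Anchoring.** The intervention is offered at a refill visit, so the
anchor dispensing is a renewal epoch: the pre-index chain is generated
*backward* from the anchor (each earlier dispensing sits covering + gap
days before its successor) and the post-index chain forward from it.
This makes the expected PDC of both windows computable exactly by a
renewal-equation dynamic program (`refill_model.expected_pdc`):
forward, the probability a window day is uncovered convolves the
renewal density with P(C ≤ offset < C + G); backward, a day is
uncovered iff the gap behind the next-more-recent epoch reaches past it.
Both are verified against direct Monte-Carlo simulation. The group- and
period-specific base gap means g are calibrated by root-finding on this
exact map so expected PDC equals the configured targets (defaults:
70.53/77.26 intervention, 73.29/77.77 control — the published adherence
levels); the study-scale cohort reproduces those means to within ~0.5
PDC points after eligibility filtering.

**Registration.** 60% of patients register the same day, the rest with
a uniform 1–60-day administrative delay; delays beyond 30 days without
an intervening refill exercise criterion 3 (≈ 13% of the default
population is excluded there).

**Events.** Qualifying exacerbation courses arrive per window as
Poisson(λ) with λ per group/period (defaults 0.68/0.73 intervention,
0.67/0.82 control — the published rates); doses and durations are drawn
from the qualifying set. Distractor prednisone courses violating the
dose or duration rule, reliever R03 dispensings, unrelated medication,
nebulizer-flagged rows, minors, non-asthma/COPD indications and
missing-status patients are emitted so every filter sees negatives.
Antimycotics are per-window Bernoulli events among ICS users (defaults
from the published prevalence table); before/after draws are
independent, so the fitted random-intercept variance on default
synthetic data is ≈ 0.

**Known-effect harness.** `simulate_known_effect` starts from a
symmetric configuration (identical groups before; a common secular
drift after: +4.48 PDC points, +0.15 exacerbations/year) and injects
the group-by-time effect on top (intervention-after PDC target raised
by the uplift; intervention-after exacerbation rate lowered by the
difference-in-differences). Registration is same-day and R03
reliever/nebulizer distractors are disabled in this harness so that no
selection mechanism (e.g. criterion 3 interacting with refill gaps, or
index dates resolving to reliever dispensings) sits between the
injected effect and the estimand — the harness validates the estimator,
not the selection realism. The recorded truth for the PDC uplift is
exact (the calibration solves the renewal equations to 1e-6), so
recovery tests compare the pipeline's difference-in-differences against
truth using only Monte-Carlo error across seeds.

**What the generator does not emulate.** Overdispersed exacerbation
counts (real SDs are ~1.2 at mean 0.7; Poisson gives ~0.85, so effect
sizes like Cohen d run larger on synthetic data than on real data),
within-patient correlation of antimycotic episodes, concurrent
multi-inhaler regimens (one maintenance chain per patient keeps the
calibration exact; the "at least one" union over multiple products is
exercised by fixtures instead), seasonal refill patterns, and
informative selection into the intervention (the published groups
differ in age/gender; the generator reproduces those marginals but not
a severity-driven offer mechanism). Passing tests therefore demonstrate
correctness of the estimators under the stated assumptions, not
robustness to these real-data features.

## Problem sizes and numerical conventions

The test suite validates at scales chosen to balance Monte-Carlo
resolution against runtime: marginal checks at 12,000–20,000 patients
(3 SEs), type-I error over 1,000 null simulations (band 3.5–6.5% around
the nominal 5%), parameter recovery over 200 seeds of 6,000-patient
cohorts (2 Monte-Carlo SEs), GLMM interaction recovery over 30 seeds of
1,500 patients, and oracle equivalence on 1,000 randomized small
patients (exact) plus a frozen 40-patient likelihood-grid fixture
(1e-3). The acceptance script uses 50 recovery seeds and reports the
values it computes. Date arithmetic is integer days since epoch
internally; all files use ISO-8601 dates; the PDC interval-union merge
sorts by start day and is exactly equivalent to a day-scan (property-
tested). Calibration root-finding uses Brent's method to xtol 1e-6 on
the gap mean.
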