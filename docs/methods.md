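# Methods

`sarcoma_cea` implements a two-year cost-utility decision model comparing
two first-line chemotherapy strategies for advanced soft-tissue sarcoma
(ASTS) — the doxorubicin/ifosfamide combination versus trabectedin
monotherapy — from the perspective of the publicly funded health systems
of Italy, Spain and Sweden. This note records the model, its
assumptions, the numerical conventions, and what the synthetic inputs do
and do not establish.

## The cohort model

A 65-year-old cohort enters in progressive disease (PD) and starts
first-line chemotherapy. The model is a deterministic Markov cohort
propagation over 24 monthly cycles with health states CR, PR, SD, PD and
death; one model cycle equals one chemotherapy cycle equals one month.

* **Response resolution.** Best response is resolved at the end of cycle
  3 of each treatment line: the PD mass splits into CR/PR/SD or stays in
  PD according to the line's response probabilities. First-line
  non-responders switch to second-line chemotherapy; second-line
  non-responders move to palliative care only.
* **Tunnel states.** Responders occupy a response state for its median
  response duration, enforced by chains of one-month tunnel
  compartments. Median months are converted to whole cycles by
  round-half-up (15.44 → 15; 8.75 → 9). Relapse from a first-line
  response leads to second-line treatment; relapse from a second-line
  response leads to palliative care. Tunnels that outlast the horizon
  are censored at 24 cycles.
* **Second line as a mixture.** The second-line course is the
  probability-weighted mixture of the country's second-line regimens
  (response probabilities, durations, toxicity, delivery, drug costs and
  mortality are all mix-weighted). The mixture response simplex is
  renormalised after weighting; mixture durations are weighted means of
  the component medians.
* **Mortality.** Background (age-related) mortality applies in every
  alive compartment, from an age-indexed life table converted to a
  constant monthly hazard within each age year. Cancer-related mortality
  applies only in PD-type compartments (on-treatment PD and palliative
  care) as a constant monthly excess hazard per (regimen, line); the
  palliative hazard continues the failed line's mixture hazard (the
  first-line hazard in the no-second-line scenario, which is why that
  scenario's QALYs are country-invariant).
* **Event ordering.** Within a cycle, death competes first; response
  resolution and tunnel advance act on survivors. The same ordering is
  used by the patient-level microsimulation oracle, making cohort
  occupancy the exact expectation of simulated paths.
* **Accounting conventions.** Occupancy during month *t* accrues
  occupancy-weighted state utility / 12. Utilities (time trade-off
  valuation): CR 0.60, PR 0.51, SD 0.43, PD 0.30, death 0. Costs and
  QALYs in the second year are discounted by a single annual step
  1/1.03; there is no half-cycle correction.

## Survival calibration

Published survival for each regimen/line is summarised as (time,
survival) anchor points. `fit_hazard` fits a line of best fit on the
log-survival scale: the default exponential form is a through-origin
least-squares fit (slope = −rate); a Weibull option linearises
log(−log S) on log t. The background hazard is netted out under additive
competing hazards, clamped at zero with a warning. Noiseless exponential
points recover the rate to 1e-10; under additive survival-scale noise
σ = 0.02 on 24 monthly points the fitted-rate error stays below 0.01
(spread measured over 200 seeded replicates).

## Costing

Costs accrue in the ten reporting categories of the two-year breakdown
(diagnosis, first-/second-line cytotoxics, evaluations, hospitalisation,
outpatient attendance, per-cycle tests, pre/post-chemotherapy
medication, palliative care, toxicity management); the grand total is
always the exact category sum.

* **Drug acquisition** uses a fixed body surface area of 1.8 m²
  (configurable) and whole-vial dispensing with wastage: the dispensed
  vials are the cheapest integer combination of the country's vial
  strengths covering the dose. Mesna is co-dispensed at the ifosfamide
  dose for ifosfamide-containing regimens and booked with cytotoxics.
* **Course structure.** Every patient on a line receives the three
  evaluation cycles; responders continue to the mean six-cycle course
  during their first three tunnel months. Expected dose reduction
  (uptake 18% × magnitude 23%, from course cycle 4) multiplies
  acquisition costs by 0.9586.
* **Delivery.** Admissions and outpatient attendances per cycle follow
  the regimen catalogue; the doxorubicin/ifosfamide admission length is
  country-specific (3 days in Italy and Sweden, 4 in Spain). A regimen
  deliverable either as an admission or as attendances is costed 50/50.
  Clinician visits during treatment are considered part of the
  admission/attendance tariffs; follow-up visits and tests (every 4.5
  months for responders off treatment) are booked under evaluations.
* **Events.** Diagnosis is charged once at entry; each line's response
  evaluation bundle once per evaluated patient; expected toxicity
  management (probability-weighted sum of the four grade-3/4
  haematological event costs) once per course started; palliative care
  as a one-off on entry (configurable). Resources without a price in a
  country's tariff list cost zero (e.g. non-febrile neutropenia
  management in Sweden).
* **Interview ranges** (diagnostic work-up proportions, evaluation and
  follow-up test proportions, follow-up interval, dose-reduction uptake)
  are fixed at their mid-range point estimates and are individually
  overridable in `resource_use.yaml`.

## Incremental analysis

The reference strategy is doxorubicin/ifosfamide, the comparator
trabectedin; Δcost and ΔQALY are reference minus comparator and the ICER
is their ratio, undefined at ΔQALY = 0 (no division). Dominance is
classified over the four sign quadrants. ICERs are reported to the
nearest euro; the underlying arithmetic is at full precision.

## Sensitivity analysis

**Probabilistic.** Each of 10,000 iterations redraws every uncertain
input reaching the two strategies: probabilities and utilities from beta
distributions, costs and resource quantities from gamma distributions,
both parameterised by method of moments around the point estimate. No
dispersion is published, so the default standard error is 20% of the
mean (overridable). The four response probabilities are drawn
independently and renormalised to the simplex — an approximation to a
Dirichlet, documented as such. Utilities are drawn independently, so
sampled sets may transiently violate the CR ≥ PR ≥ SD ≥ PD ordering.
Cancer hazards are calibration outputs, not sampled inputs, and are held
fixed. Iteration *i* uses the stream `default_rng([seed, i])`, so
results are bit-reproducible and order-independent. The acceptability
curve reports, per willingness-to-pay threshold, the fraction of
iterations with positive net monetary benefit λ·ΔQALY − Δcost.

Note a discretisation effect: medians sitting exactly on a rounding
half-boundary (e.g. 8.75 months) flip their tunnel length under
arbitrarily small jitter, so PSA means need not converge to the base
case as dispersion → 0 at such points.

**Deterministic.** One-way scenarios move a single addressed parameter
to 20% below/above base. Overrides of one simplex component rebalance
the remaining components proportionally; mix overrides likewise. The
standard battery covers response durations and probabilities, the
second-line trabectedin share, admission length, the three key drug
prices, grouped toxicity/premedication costs, palliative care and the SD
and PD utilities, ordered by ICER range width (tornado order).

## Synthetic inputs and what they establish

The published analyses do not tabulate their survival curves, their
national life tables, or the raw interview resource quantities. The
synthetic module therefore provides:

* **Survival points** from a known exponential hazard plus clipped,
  monotonised Gaussian noise — used to demonstrate calibration recovery,
  not to reproduce the published curves.
* **A life table** with annual mortality 0.02 × 1.1^(age−65) from age
  65 — a plausible stand-in; no headline result depends on its exact
  values.
* **Fixture cancer hazards** calibrated once so the modelled two-year
  death probabilities land in the published 0.42–0.47 band (monthly
  rates: first-line 0.042 / 0.032; second-line 0.031–0.046). Regimens
  without published second-line survival take donor averages mirroring
  the published imputation rules.
* **Random parameter packs** (log-normal jitter, simplexes
  renormalised) that always pass the pack validators — used for
  property testing.
* **A microsimulation oracle** walking individual patients through the
  same state space, event ordering and cost structure; cohort outputs
  must match its Monte-Carlo means within sampling error.

Because the mortality curves and resource quantities are stand-ins, the
per-category cost amounts and per-strategy QALY levels are approximate
by construction; what the fixtures are calibrated to support are the
directional findings (reference dominance in all three countries, the
no-second-line QALY ordering, and an acceptability probability above 0.5
at €35,000/QALY) plus all worked examples that derive from the published
tables themselves.

## Known limitations

* Average-patient model: no heterogeneity in age, sex, histology or
  body surface area; no third-line treatment; no indirect/societal
  costs; two-year horizon with censoring.
* The published imputed toxicity rows cannot be reproduced from their
  stated donor rows (the printed values are carried in the fixtures
  instead); the printed second-line duration averages reproduce exactly
  under half-up rounding with unobserved (zero) donor durations
  excluded.
* Printed probability rows that drift from 1.0 by print rounding are
  renormalised proportionally at load; drift beyond 0.02 is an error.
* Problem sizes used by the test-suite and the acceptance script —
  20,000 microsimulated patients, 200 calibration replicates, 10,000
  PSA iterations — were chosen to keep Monte-Carlo error well below the
  assertion tolerances.
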