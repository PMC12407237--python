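# Methods

## Model structure

The model is a three-state Markov cohort (Undiagnosed, Diagnosed, Dead) in
3-month cycles. Everyone starts Undiagnosed at the onset age and remains
there until diagnosed or dead; Diagnosed never reverts; Dead is absorbing.
The trace records state occupancy at each cycle start and the mass newly
entering Diagnosed each cycle. The horizon is "lifetime", made operational
as: stop when the attained age passes the life-table maximum (the table is
closed with qx = 1 there, so the cohort is extinguished) or when alive mass
falls below 1e-8.

Within a cycle, death is applied before diagnosis (diagnosis reaches cycle
survivors only). The ordering is a modelling convention, exposed as a flag
(`death_first`) on `run_cohort`; at the death rates involved the difference
is far below every tolerance used here. No half-cycle correction is applied:
costs attach to occupancy at cycle start. With quarterly cycles the maximal
effect of a half-cycle correction on a cumulative total is about half of one
cycle's cost (~0.5%), smaller than any uncertainty band in play.

## Diagnosis process

The per-cycle diagnosis probability is calibrated directly from the target
mean time to diagnosis T (default 8.5 years):

* `continuous` (default): `p = 1 − exp(−c/T)`, the discretized exponential
  waiting time, consistent with the constant-hazard convention used for all
  other rate/probability rescaling;
* `geometric`: `p = c/T`, matching the mean of the discrete geometric in
  cycle units; rejected when `c ≥ T` since a delay model needs `p < 1`.

Diagnoses during a cycle are timed at the cycle midpoint when summarizing
the realized mean delay, so the no-mortality trace recovers T to well within
one half-cycle (the residual bias is the mass censored at the horizon,
~2e-4 of the cohort).

Diagnostic test sensitivity and specificity are carried as inputs because
they belong to the diagnostic pathway this model abstracts, but the
reduced-form calibrated hazard is what governs transitions: in a cohort
assumed a priori to have the disease, specificity has no transition to act
on, and no mechanism linking sensitivity to the per-cycle hazard is
specified. They are therefore inert, documented, user-overridable inputs;
the calibrated-delay route keeps the 8.5-year mean exact.

## Mortality

Background mortality comes from an annual life table (age, sex, qx), looked
up at the floor of attained age (life tables are annual; interpolation would
add complexity with negligible effect at this scale). Excess disease
mortality enters as a standardized mortality ratio on the hazard scale,
`1 − exp(−SMR·h·c)` with `h = −ln(1 − qx)`, which keeps probabilities valid
for any SMR > 0; the same SMR applies in both alive states, since a single
per-sex value is specified. An SMR below 1 is accepted with a warning (it
can legitimately arise in PSA draws).

## Costing

Costs accrue only while Undiagnosed — the quantity of interest is the cost
of the delay, and post-diagnosis costs are out of scope — and are
discounted at 3.5%/year, `(1+r)^(−t)`, compounded by cycle. Three
perspectives are kept separate and sum to the total:

* **healthcare** (NHS): GP visits × unit cost + physiotherapy visits × unit
  cost + Σ comorbidity onset probability × management cost, per cycle;
* **out-of-pocket**: OTC medication with each item's monthly cost capped at
  the prescription charge (£9.35) and the annualized sum capped at the
  prepayment certificate (£108.10), spread evenly over the four cycles
  (the cap is annual; even spreading is the least-informative allocation);
  practitioner (chiropractor/osteopath) fees; return taxi travel (2 × one-way
  fare) for every practice visit, GP and physiotherapy included; and
  non-prescribed exercise;
* **productivity** (human-capital): for the employed fraction, absenteeism
  hours × sex-specific gross median hourly wage + presenteeism cost +
  turnover cost, stopping at the retirement age (default 66, configurable —
  the work-loss cutoff is a design choice, since early retirement is an
  explicit input but no cutoff for the other work terms is stated);
  early-retirement and unpaid-care expected costs continue at all ages.

Currency is held at full floating precision; rounding to pennies and
percentage rounding to one decimal happen only at render time.

Two per-person "annual cost" summaries are computed, because the mapping
from a cumulative lifetime figure to an annual one is genuinely ambiguous:
the cumulative discounted total divided by the realized mean delay (used
for the national extrapolation) and the undiscounted first-year cost. Both
are reported and labelled.

## Probabilistic sensitivity analysis

Each uncertain input carries a distribution: beta for proportions and
probabilities, gamma for nonnegative costs, counts and wages (standard
health-economics practice), uniform or fixed where appropriate. With a 95%
CI, the beta/gamma shape is found by root-finding on the concentration so
the central 95% quantile span matches the CI width while the mean is
preserved exactly; with only a ±20% band, the band is read as an
approximate 95% interval (sd = mean × 0.20/1.96). Structural constants
(cycle length, onset age, discount rate, policy caps, retirement age,
populations) are not varied. Draws are independent across parameters (no
correlation structure is specified) and across iterations, each iteration
using a substream spawned from the master seed, so results are bitwise
reproducible and order-independent. Draws violating the joint invariants
(e.g. a sampled delay below the 1-year gold standard) are rejected and
redrawn; more than 10% rejections aborts with a diagnostic. Summaries are
the empirical mean and nearest-rank 2.5/97.5 percentiles, matching the
granularity of 1000 draws.

## National extrapolation

Total annual cost = per-person annual cost × prevalent population ×
undiagnosed fraction. Three populations are built in: the patient-society
estimate (220 000) and the 0.3%/1.2% prevalence bands applied to the UK
adult population (53 930 490, mid-2022), giving exactly 4× scaling between
the two prevalence scenarios. The default undiagnosed fraction is 0.8335,
the value implied by the published national-table arithmetic; the rounded
0.834 is available by override (the two differ by <0.01% in the totals).
The published table footnote's 83.4%-per-year figure would, under a
constant hazard, imply a mean delay near 5.6 years, inconsistent with the
8.5-year mean that governs cohort dynamics; the model treats them as
independent inputs (delay drives the cohort, the fraction drives
extrapolation), both user-settable.

## Synthetic inputs

The generator stands in for input tables that were never publicly
deposited. It keeps two provenance classes strictly apart: published
constants (onset 26, 64% male, delay 8.5 y, SMRs 1.630/1.380, discount
3.5%, caps £9.35/£108.10, prevalences 0.3%/1.2%, populations, fraction
0.8335) are emitted verbatim; everything else is drawn uniformly within
documented ±10% plausible ranges around realistic UK-scale magnitudes
(PSSRU-scale unit costs, survey-scale visit frequencies, wage-survey-scale
hourly pay, report-scale productivity costs). The ranges were chosen once
so that the default scenario's cumulative total lands inside the published
95% CI of the corresponding study-scale estimate — an order-of-magnitude
anchor, not a fit. The stress scale pins every synthetic value to its upper
bound, which provably dominates the default total (costs enter linearly).

The life table is Gompertz–Makeham, `q(age) = 1 − exp(−(a + b·e^{c·age}))`,
with female coefficients drawn in UK-plausible ranges and male mortality
obtained by scaling the female background and senescent terms up, enforcing
male ≥ female mortality at every age. The table runs from age 0 to 100 and
closes with q = 1.

What the synthetic data does **not** emulate: real ONS life-table shapes at
young ages, correlations between inputs (e.g. wages and employment),
inflation-era price dynamics, or severity stratification. Tests passing on
synthetic inputs demonstrate the engine's correctness (conservation,
calibration, linearity, oracle equivalence), not the empirical accuracy of
any particular cost figure for the UK.

## Numerical choices

* `expm1`/`log1p` throughout the hazard algebra to avoid cancellation at
  small probabilities.
* Occupancy conservation is enforced at 1e-10 per cycle; additivity of the
  cost categories at 1e-9 relative.
* The microsimulation oracle (200 000 individuals) is compared per cycle at
  3 Monte-Carlo standard errors wherever the Gaussian SE is meaningful
  (expected cell count ≥ 25); in the depleted tail, where counts are
  Poisson-scale and serially correlated, the fraction of cells beyond 3 SE
  is bounded below 1% instead — a fixed band there would reject a correct
  model with non-negligible probability.
* Percentiles are nearest-rank on sorted draws (simple, reproducible).
* Problem sizes used by the default test run: cohort traces of ~298 cycles
  (ages 26–100), 50 000-individual microsimulation in the unit suite and
  200 000 in the acceptance suite, PSA of 1000 draws in the acceptance
  script and 15–200 in unit tests — sizes at which every check is stable
  and the whole suite runs in seconds.

## Known limitations

* The cohort is homogeneous at onset (no severity, no radiographic /
  non-radiographic split, no onset-age distribution).
* Post-diagnosis costs, caregiver costs and mental-health talking therapies
  are out of scope.
* The category composition of the synthetic default differs from the
  published study-scale composition (productivity dominates more strongly
  here); only the total is anchored to the published interval, since the
  published category-level inputs are not public.
* The published mixed-cohort total exceeds both sex-specific totals, so it
  cannot be a convex combination of the published sex-specific runs;
  `mix_cohorts` implements the convex combination and this package makes no
  attempt to reconcile that aggregation. Similarly, the published
  healthcare share prints as 3.5% where the printed costs give 3.63%;
  shares here are always recomputed from costs.
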