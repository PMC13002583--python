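# Methods

This note documents the model as implemented: its structure, assumptions,
parameter conventions, numerical choices, and the design decisions taken
where the underlying published description leaves the structure open.

## Cohort, horizon and perspective

A closed cohort of 1,000 treatment-naive cACLD patients (no prior
decompensation, no contraindication to NSBBs or ligation) is followed over
five annual cycles from a healthcare-system perspective.  Only direct
medical costs are counted, in 2022 USD.  Costs and QALYs are discounted at
3.5% per year.

## Decision tree (cycle 1)

Each strategy's screening tests resolve within the first cycle and
distribute the cohort over initial Markov states:

| Arm | Tests for all | Endoscopy for | Initial states |
|---|---|---|---|
| universal | endoscopy | everyone | HRV→NSBB/ligation (0.8/0.2), rest→endoscopic follow-up |
| selective | elastography + platelets | criteria non-meeters | meeters: no-HRV surveillance or missed HRV; non-meeters as universal |
| LSM ≥ 25 scenario | elastography | LSM < 25 stratum | ≥25 kPa: NSBB states; <25 kPa as universal |

Triage classification probabilities (probability of meeting criteria, NPV,
PPV) are derived from prevalence/sensitivity/specificity by Bayes' rule and
always carried at full precision; the familiar two-decimal values
(0.26/0.98/0.26) are display rounding.  "Sensitivity" is read as the
probability that a true HRV patient is *flagged for endoscopy* (does not
meet the low-risk criteria); only this reading yields a 26% meet rate from
the tabulated accuracy values.

## Markov engine

Eight base states plus two scenario-only states.  Within-cycle composition,
defined once and shared verbatim with the microsimulation:

1. other-cause death (0.034/yr) first;
2. survivors bleed at the state's annual probability
   (missed HRV 0.10, NSBB 0.068, ligation 0.043, all no-HRV states 0 by
   default — see "background bleeding" below);
3. fatal bleed with probability 0.022, otherwise post-bleed;
4. remaining mass stays in state.

The ordering (death before bleed) is a modelling choice; the published
description states independence of the two risks but not an ordering.  It
is isolated in one function so alternatives are one-line swaps.

Post-bleed patients are absorbing for bleeding (one bleed per patient
maximum) and carry the post-bleed utility 0.54 chronically for all
remaining cycles, because it is tabulated as a health-state utility rather
than an event disutility.  Missed-HRV patients remain untreated for the
whole horizon unless they bleed; an optional flag (`detect_missed_hrv`)
moves them into treatment at the next cycle for exploration.

Cost schedules per cycle: NSBB states pay the annual drug cost (\$52.68);
the ligation state pays an annual endoscopy plus the ligation procedure
biennially from initiation (cycles 1, 3, 5); endoscopy-negative follow-up
repeats endoscopy every two years after the initial exam (cycles 3, 5);
surveillance and missed-HRV states pay elastography + platelets (\$21.28)
every cycle; each bleed event costs \$1,934.52, which subsumes the
post-bleed endoscopy.  Decision-tree test costs are charged at cycle 1.

Discounting is end-of-cycle — cycle *t* accruals are multiplied by
(1.035)^(−t), *t* = 1..5 — with no half-cycle correction, and accrual uses
the post-transition occupancy of each cycle (deaths during a cycle accrue
nothing for it).  In the no-event limit this yields the closed-form annuity
QALY = *u* × Σ (1.035)^(−t), which the tests assert exactly.

## Economic metrics

ICER = ΔC/ΔE with explicit dominance flags replacing the ratio when one
strategy is cheaper and more effective, and an explicit undefined flag for
equal effectiveness.  NMB = λE − C at λ = \$12,714.11/QALY.  A
three-strategy efficiency frontier with simple and extended dominance is
provided for co-plotting the scenario arm.

## Deterministic sensitivity analysis

Parameters carry their published ranges verbatim; sweeping
prevalence/sensitivity/specificity recomputes the derived triage quantities
(sweeping NPV/PPV directly is rejected with guidance, since they are not
free parameters).  The tornado ranks parameters by the absolute span of the
NMB difference between arms — not by ICER span — because dominance regions
make ratio spans ill-defined.  Threshold searches bisect a signed criterion
margin to 0.01 USD (costs) or 0.001 (probabilities); the endoscopy-cost
break-even uses *equal per-capita total cost* as its criterion (an
NMB-equality criterion is also registered).  Two-way grids over triage
sensitivity × specificity report a boolean cost-effectiveness indicator at
the GDP WTP.  Default resolutions: 50 points one-way, 41×41 two-way
(configurable; the CLI uses coarser grids by default for speed).

## Probabilistic sensitivity analysis

Families: beta for probabilities and utilities, gamma for costs, triangular
available where moment fitting fails.  Fitting is method-of-moments
treating the printed range as a 95% interval, SE = (high − low)/(2×1.96).
Two tabulated probabilities (the NSBB/ligation treatment split and
other-cause mortality) print the full support [0, 1] as their range, which
carries no distributional information and breaks both the beta and the
mean-consistent triangular fit; these fall back to a ±20% interval around
the mean — the model's default variation rule for parameters without an
informative range.  All parameters are drawn independently (no correlation
information is published); the treatment split stays normalised because the
ligation share is defined as the complement.  Out-of-domain draws are
rejection-resampled, capped at 1,000 attempts.  The CEAC is evaluated on a
0–3×GDP grid in 200 steps, with ties broken toward the reference arm.
10,000 iterations take ≈10 s; a fixed generator seed makes output
bit-reproducible.

The tabulated untreated-HRV utility (0.72) lies outside its own printed
range (0.75–0.90); both are used exactly as printed.  This only affects the
DSA endpoints (the beta fit uses the mean and the range *width*).

## LSM ≥ 25 kPa scenario

The published description prints scenario outputs but not the stratum-level
inputs behind them, so the scenario is parameterised explicitly with
documented illustrative defaults: 30% of the cohort above 25 kPa, HRV
prevalence 40% within that stratum, 7.5% of the stratum misclassified
(receiving NSBBs without true CSPH, from a quoted 5–10% plausible band) at
utility 0.73 (the no-HRV utility minus a small NSBB side-effect decrement).
The low-stratum HRV prevalence is derived so the strata average to the
overall 20%.  Stratum mass conservation is validated whenever the scenario
arm is allocated or run — not at parameter construction, so base-arm
analyses (e.g. PSA prevalence draws) are not constrained by scenario
feasibility.  Scenario outputs are therefore exploratory, not reproduction
targets.

## Microsimulation oracle

The individual-level simulator draws every allocation and disease event as
a Bernoulli trial at exactly the cohort engine's probabilities, using the
same composition rule, schedules and discounting, so the cohort expectation
and the microsimulation mean are equal by construction.  Agreement within
3 Monte Carlo standard errors at n = 200,000 is asserted in the tests, as
is 1/√n shrinkage of the standard error across n = 10³–10⁵.  The simulator
emulates sampling variability only: patients are homogeneous apart from
HRV status and triage outcome — no age structure, etiology mix, adherence
decay, or secular trends in prices and practice.  Passing oracle tests
therefore validates the engine's arithmetic, not the transferability of the
inputs to any real population.

## Problem sizes

Default analyses use the 1,000-patient cohort, 10,000 PSA iterations and
200,000 microsimulation patients; these sizes give Monte Carlo standard
errors well below the decision-relevant differences while keeping the full
test suite and the acceptance script in the tens of seconds.

## Reconstruction fidelity and known limitations

The acceptance checks (`tests/test_acceptance.py`, `scripts/acceptance.py`)
compare this reconstruction against the published base-case figures.  The
exact-arithmetic anchors reproduce: triage probabilities 0.26/0.98/0.26,
the 26% endoscopy sparing, all 200 HRV patients identified by universal
screening, and the published ICER arithmetic (69/0.0328 → \$2,103.66).

The model-reconstruction anchors do not reproduce from the printed inputs,
and the discrepancies are structural rather than tuning error:

* **QALYs.**  The published per-person effectiveness (3.4452 universal)
  exceeds the zero-mortality discounted upper bound implied by its own
  inputs: with the initial utility mix 0.7388 and five discounted years
  (annuity 4.515), no survival path reaches 3.4452 once the tabulated
  3.4%/yr other-cause mortality removes ≈16% of the cohort by year 5.  The
  engine computes ≈3.00 per person.
* **Direction of the comparison.**  At the printed prices, annual
  non-invasive monitoring is cheaper than biennial endoscopy, and the
  printed untreated-HRV utility (0.72) exceeds the treated utilities
  (0.65/0.67), so the selective arm comes out slightly cheaper *and*
  slightly more effective (dominant, ΔC ≈ −\$21, ΔE ≈ +0.0009) instead of
  costing \$69 more for 0.0328 extra QALYs.  Downstream anchors shift
  accordingly: the endoscopy-cost break-even computes to ≈\$64 (published
  \$192.59), the cost-effectiveness region covers the whole prevalence
  range (published threshold 42%), the PSA probability of
  cost-effectiveness is ≈83% (published 57.2%), and the acceptability
  crossover sits at WTP 0 (published \$4,322).
* **Bleeding events.**  Treated and missed HRV patients generate ≈50
  expected bleeds per arm over five years; the published 80/90 counts
  require a bleed-generating mechanism in endoscopy-negative/no-HRV states
  whose rate is not printed.  An optional background bleed probability
  (`p_bleed_background`, default 0) exposes that mechanism without
  inventing a calibrated value.

These comparisons are computed, not asserted: the corresponding acceptance
tests fail by design at the published anchors and pass for every
structural property (conservation, normalisation, one-bleed maximum,
oracle duality, determinism, annuity limits).  No input was adjusted toward
the published outputs.
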