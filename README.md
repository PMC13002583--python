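# varscreen

A decision-analytic model of **screening strategies for high-risk
esophagogastric varices (HRV)** in patients with compensated advanced chronic
liver disease (cACLD), built for health economists and hepatology researchers
evaluating non-invasive triage policies.

Two base strategies are compared from a healthcare-system perspective:

* **Universal screening** — every patient undergoes upper endoscopy;
  confirmed HRV patients start primary prophylaxis (non-selective
  beta-blockers, NSBBs, or endoscopic band ligation), endoscopy-negative
  patients repeat endoscopy biennially.
* **Selective screening** — every patient first receives transient
  elastography and a platelet count; patients meeting the Baveno low-risk
  criteria (liver stiffness < 20 kPa and platelets > 150×10⁹/L) skip
  endoscopy and enter annual non-invasive surveillance, the rest proceed to
  endoscopy. False negatives leave some HRV untreated at an elevated
  bleeding risk.

A third arm models the newer stiffness-stratified policy: patients with
LSM ≥ 25 kPa (ruled-in clinically significant portal hypertension) start
NSBBs without endoscopy.

## The model

A first-cycle decision tree allocates a cohort of 1,000 patients using the
triage accuracy of the criteria.  With prevalence $p$, sensitivity $se$
(probability an HRV patient is flagged for endoscopy) and specificity $sp$
(probability a non-HRV patient is spared):

$$P(\text{meet}) = p(1-se) + (1-p)\,sp,\qquad
\text{NPV} = \frac{(1-p)\,sp}{P(\text{meet})},\qquad
\text{PPV} = \frac{p\,se}{1 - P(\text{meet})}.$$

A Markov cohort engine then runs annual cycles over a five-year horizon
across eight health states (no-HRV surveillance, no-HRV endoscopic
follow-up, HRV on NSBB, HRV on ligation, missed HRV, post-bleed, death from
bleeding, death from other causes).  Within each cycle, other-cause death
($p_{d}$ = 0.034/yr) strikes first; survivors bleed with a state-specific
annual probability (0.10 untreated, 0.068 on NSBBs, 0.043 after ligation); a
bleed is fatal with probability 0.022.  Each patient bleeds at most once.
Costs (2022 USD) and utilities accrue per cycle and are discounted at 3.5%
per year, end-of-cycle, without half-cycle correction.

Strategies are compared by the incremental cost-effectiveness ratio
$\mathrm{ICER} = \Delta C / \Delta E$ against a willingness-to-pay threshold
$\lambda$ = \$12,714.11/QALY, and by net monetary benefit
$\mathrm{NMB} = \lambda E - C$.  Deterministic sensitivity analysis (one-way
sweeps, NMB-span tornado, bisection break-even search, two-way accuracy
grids) and a 10,000-iteration probabilistic sensitivity analysis (beta
distributions for probabilities/utilities, gamma for costs, fitted by method
of moments from the published ranges) quantify decision uncertainty.  An
individual-level microsimulation draws Bernoulli patient trajectories at the
same probabilities and serves as a stochastic oracle for the cohort
arithmetic.

## Worked example

```python
import varscreen as vs

params = vs.load_parameters()          # published base-case inputs
res = vs.compare_strategies(params)    # universal vs. selective
print(res.summary())
```

prints

```
{'reference_cost': 406.46, 'reference_qaly': 3.0008,
 'comparator_cost': 385.58, 'comparator_qaly': 3.0017,
 'incremental_cost': -20.87, 'incremental_qaly': 0.0009,
 'icer': None, 'dominance': 'comparator dominant'}
```

Read: at the tabulated input values the universal arm costs \$406.46 per
person over five discounted years for 3.0008 QALYs, while the selective arm
costs \$385.58 for 3.0017 QALYs — the selective strategy is *dominant*
(cheaper and marginally more effective), so no ICER is reported.  The
dominance arises directly from the printed unit prices (annual elastography
+ platelets, \$21.28, is cheaper than biennial endoscopy at \$96.73) and the
printed utility of untreated HRV (0.72) exceeding that of treated HRV
(0.65–0.67).  See `docs/methods.md` for how this reconstruction relates to
the published base-case figures used as anchors by the acceptance checks.

The same analyses are available from the command line:

```sh
varscreen --out out base-case      # cost/QALY table, CE plane, cohort traces
varscreen --out out dsa            # tornado, break-even thresholds, two-way grid
varscreen --out out psa --seed 1   # PSA scatter, CEAC, P(cost-effective)
varscreen --out out scenario       # LSM >= 25 kPa NSBB-initiation arm
varscreen --out out simulate --n-patients 1000 --seed 1   # microsimulation
```

Every command writes CSV/JSON outputs, figures and a run manifest (config
hash, seeds, versions) for reproducibility.

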