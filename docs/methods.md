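# Methods

## Model structure

Each screening strategy is a finite decision tree evaluated by expectation:
the expected cost and expected QALY of a strategy are the probability-weighted
sums over all root-to-leaf paths.  Chance nodes partition the cohort — by
BRCA1/2 carrier status, family-history (FH) status, management arm, and
finally cancer outcome — and every path terminates in exactly one of five
states: early-stage ovarian cancer (OC), late-stage OC, early-stage breast
cancer (BC), late-stage BC, or no cancer.  The engine checks at every chance
node that branch probabilities lie in [0, 1] and sum to 1, and the flat path
enumeration agrees with the recursive expectation to 1e−10 (property-tested
against an independent brute-force summation on random trees).

The cohort is women aged 40–60; risks are cumulative to age 70, so the
horizon is 10 years with no discounting and no half-cycle correction (costs
are predominantly incurred up front and the horizon is short).

### Cancer outcome split

OC and BC are treated as mutually exclusive over the horizon (double
primaries are rare and excluded): P(OC) = risk_OC and
P(BC) = min(risk_BC, 1 − risk_OC), i.e. the two risks are additive until
they saturate the unit interval.  The clip also keeps the split a valid
distribution for extreme probabilistic-sensitivity draws.  We deliberately do
**not** condition BC risk on the absence of OC (multiplying by 1 − risk_OC):
with the baseline inputs the additive form reproduces the strategy-level
QALY totals of the reference analysis to ~2e−6, whereas the conditioned form
leaves a systematic gap an order of magnitude above rounding.

### Stage at detection

Symptom-detected cancers (everyone except identified carriers) split
early/late by the stage-mix parameters (`ratio_early_OC` = 0.30,
`ratio_early_BC` = 0.621).  Cancers arising in identified carriers — who are
under intensive follow-up in every management arm, including the
surveillance-only arm — are modelled as detected at an early stage.  This is
the model's largest structural assumption.  It encodes the purpose of
carrier identification (stage shift plus risk reduction), and it is also the
only staging convention we found that reproduces the reference per-carrier
QALY gain (≈1.83 QALYs per identified carrier, versus ≈1.66 when carriers
keep the symptomatic stage mix, a difference large enough to move the
headline ICER by ~10%).  A consequence is that carrier identification has
value even for null interventions; the structural test suite therefore
checks the no-free-lunch invariant under a degenerate stage mix
(`ratio_early_* = 1`), where all three strategies tie on QALYs when all risk
ratios are 1 and all uptakes are 0.

### Management arms

Identified carriers distribute over five arms with weights
(p20, p26, p32, p38, residual):

| arm | RR(OC) | RR(BC) | cost | first-year disutility |
|---|---|---|---|---|
| chemoprevention (RRA) | 0.53 | 0.64 | cost_rra | 0 |
| RRM only | 1.0 | 0.114 | cost_rrm | 1 − u_RRM_y1 |
| RRSO only | 0.21 | 0.49 | cost_rrso + cost_hrt | 1 − u_RRSO_y1 |
| RRM + RRSO | 0.21 | 0.05 | cost_rrm + cost_rrso + cost_hrt | sum of both |
| surveillance only | 1.0 | 1.0 | cost_periodical_examination | 0 |

The combined-surgery OC risk ratio is the RRSO value (mastectomy does not
affect ovarian risk).  Hormone replacement is bundled with RRSO because
oophorectomy in this age band routinely triggers it; periodic-examination
cost attaches only to the surveillance-only arm (the surgical arms' costs
are their procedures).  Surgical disutility is a one-year decrement
(1 − first-year utility) subtracted once from the path QALY.

### Cost attachment

All strategies: general examination for everyone and a diagnosis cost on all
four cancer leaves (early and late alike).  Population-based adds the BRCA
test for everyone; FH-based adds FH counselling for everyone and the BRCA
test for the FH+ fraction only; identified carriers add their arm cost.

### Family-history wiring

`fh_detection_convention` selects how the detected-carrier mass enters:

- **coherent** (default): FH+ women are carriers at rate p51, so p50·p51 of
  the population is detected and treated; FH− women carry at
  (p1 − p50·p51)/(1 − p50), conserving total prevalence p1.  Requires
  p50·p51 ≤ p1 (validated; infeasible PSA draws are rejected).
- **paper_compat**: costs follow the coherent tree, but the QALY expectation
  uses a detected mass of p1·p51 (FH− rate p1(1−p51)/(1−p50), still
  conserving p1).  This reproduces the reference FH-strategy QALY gain,
  which is not consistent with the coherent mass given the per-carrier gain
  implied by the population-based strategy.  Both wirings give the same
  FH-strategy cost; the coherent wiring gives a ~2.5× larger QALY gain and
  hence a more favourable FH ICER.

A provable consequence of prevalence conservation: the FH-vs-symptom QALY
difference equals (detected mass) × (per-carrier gain) and is positive for
every p50 > 0 — there is no low-p50 regime in which FH-based testing loses
QALYs under either wiring.

## Parameters and uncertainty

All values live in a single frozen `ParameterSet` (42 varied quantities plus
horizon, WTP and the wiring switch) with config round-tripping via flat
YAML.  Deterministic ranges: reported 95% CI where available, otherwise
±10% (±30% for costs), clipped to [0, 1] for bounded quantities.  One-way
variations that would break structural validity (an uptake CI end pushing
the four uptakes past 1; p50/p51/p1 feasibility in coherent mode) are capped
at the feasibility boundary.

PSA distributions by role, fitted by method of moments with mean pinned to
the base value: beta for probability-like quantities (including risk
ratios), gamma for costs, log-normal for utilities and survival (draws
clipped at 1; the clip's mean shift is negligible at these spreads).  SDs:
(CI width)/3.92 when a CI is reported, else 0.10 × base for bounded
quantities and 0.30 × base/1.96 for costs (reading the ±30% deterministic
range as a 95% interval).  These SD conventions are the analysis's largest
distributional assumption; no published SDs exist to check them against, so
probabilistic outputs (CEAC fractions, EVPI magnitudes) are more
convention-dependent than the deterministic results.  Parameters at a
support boundary (a utility of 1, a risk ratio of 1) are degenerate.
Parameters are sampled independently; structurally invalid draws (uptake sum
> 1, and p50·p51 > p1 in coherent mode) are rejected and redrawn, which is
the only correlation the model induces.

## Numerics

- Chance-node sum tolerance 1e−9 (residual branches are constructed as
  1 − Σ others, so sums are exact by construction); path-probability
  conservation is property-tested at 1e−12.
- ICER with ΔQALY = 0 returns a signed-infinity sentinel plus a
  classification; dominance is classified, and raw signed ICERs are emitted
  only in the DSA/scenario exports.
- Days conversion uses 365 days/year.
- Threshold (break-even) search uses Brent's method on ICER(x) − target and
  verifies |ICER − target| < 0.5 ¥/QALY at the root; a missing sign change
  in the bracket is an error.
- EVPI is computed as the mean per-iteration regret of the best-on-average
  strategy, which is non-negative term by term and exactly zero under
  degenerate distributions (avoiding cancellation between O(1e6) NMB means).
- CEAC ties (measure zero in practice) are split equally.
- The WTP grid default is 0–600,000 ¥/QALY in 1,000 steps.

## Synthetic data

`random_parameter_set` draws structurally valid parameter sets either near
the base case (±20% jitter) or broadly over plausible ranges, repairing the
uptake-sum and FH-feasibility constraints; it emulates the *structure* of
the input space, not the epidemiology of any real population, so passing
property tests demonstrates engine correctness (conservation, monotonicity,
oracle agreement), not real-world validity.  `random_tree` generates small
random chance trees whose expectations are computed at generation time by an
independent path summation, serving as the oracle for the evaluation engine.

## Problem sizes

The bundled analyses are small: the three strategy trees have 10–40 paths;
the tornado covers 42 parameters (84 re-evaluations per comparison); the PSA
default is 5,000 iterations, and the acceptance pipeline (base case, all
scenarios, threshold searches, one 5,000-iteration PSA) completes in well
under a minute on a single CPU.

## Known limitations

- No Markov extension: risks are single 10-year cumulative probabilities,
  with no age-dependent hazards, no cascade testing of relatives, and no
  post-diagnosis treatment economics.
- Variants of uncertain significance are treated as wild-type.
- The carrier stage-shift assumption (all early) is an upper bound on the
  stage benefit of surveillance.
- The FH cost/QALY wiring ambiguity is exposed rather than resolved; results
  sensitive to it (the FH ICER, its break-even test price, probabilistic
  quantities involving the FH strategy) should be read per convention.
- Probabilistic outputs depend on the SD conventions above; the pairwise
  probability that FH-based testing beats symptom-only at the threshold is
  robust across seeds (~0.80 at n = 5,000), while CEAC shares and EVPI peak
  values shift substantially under plausible alternative spreads.
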