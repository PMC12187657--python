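# brcascreen

Decision-analytic cost-effectiveness evaluation of adding **BRCA1/2
germline testing** to breast and ovarian cancer screening for Chinese women
aged 40–60, from a payer perspective over a 10-year horizon.

Three strategies are compared:

| Strategy | Who is tested | What carriers receive |
|---|---|---|
| `symptom_only` | nobody | nothing until symptoms |
| `population_based` | every woman | risk-reducing management |
| `fh_based` | women with a positive family history (FH+) | risk-reducing management |

Identified carriers distribute over five management arms — chemoprevention
(RRA), risk-reducing mastectomy (RRM), risk-reducing salpingo-oophorectomy
(RRSO, with hormone replacement), both surgeries, or intensified
surveillance — each with its own uptake rate, cancer risk ratios, cost and
first-year surgical disutility.

## Model

Each strategy is a decision tree whose root-to-leaf paths end in one of five
mutually exclusive states: early/late ovarian cancer, early/late breast
cancer, or no cancer.  For a woman with 10-year ovarian risk *r*₍OC₎ and
breast risk *r*₍BC₎:

- P(OC) = *r*₍OC₎ and P(BC) = min(*r*₍BC₎, 1 − *r*₍OC₎) — no double primaries;
- symptom-detected cancers split early/late by the symptomatic stage mix;
  cancers in carriers under active management are detected early;
- carrier risks under an arm are penetrance × risk ratio
  (e.g. *p*₁₅ · RR₍OC₎);
- leaf payoff: **QALY = horizon × 10-year survival × utility**, minus any
  first-year surgical disutility; path costs accumulate examination,
  counselling, testing, management and diagnosis costs.

Strategies are compared by the incremental cost-effectiveness ratio
ICER = ΔCost/ΔQALY against a willingness-to-pay (WTP) threshold of ¥268,200
per QALY (3× GDP per capita), or equivalently by net monetary benefit
NMB = QALY·WTP − Cost.  One-way sensitivity analysis (tornado), break-even
threshold search, scenario analysis, and probabilistic sensitivity analysis
(beta/gamma/log-normal parameter distributions, CEAC and EVPI curves) are
built in.

Because the published FH-strategy cost and QALY gain are not reproducible
from a single detected-carrier mass, two wirings are provided
(`fh_detection_convention`): `coherent` (default; detected carriers are
p50·p51 of the population, total prevalence conserved) and `paper_compat`
(costs use p50·p51, QALYs the p1·p51 mass that reproduces the published
QALY gains).  See `docs/methods.md`.

## Worked example

```bash
brcascreen --compat paper_compat base-case
```

prints

```
population_based vs symptom_only: ICER 506835 yuan/QALY (not_cost_effective)
population_based vs fh_based: ICER 542588 yuan/QALY (not_cost_effective)
fh_based vs symptom_only: ICER 185053 yuan/QALY (cost_effective)
```

and writes `base_case.csv` / `incremental.csv`.  Reading: screening plus
family-history-triaged testing costs ¥599 per woman and yields 9.5594
expected QALYs versus ¥465 and 9.5587 for symptom-only screening — about
¥185,000 per QALY gained, below the ¥268,200 threshold, so FH-based testing
is cost-effective.  Population-wide testing costs ¥4,142 per woman and buys
QALYs at roughly ¥507,000 each: not cost-effective unless the test price
falls by about half (`brcascreen threshold --parameter cost_brca_test
--comparison population_based:symptom_only --bracket 100 3600` finds the
break-even price near ¥1,869).

The same results are available as a library:

```python
from brcascreen import default_parameters, evaluate_all, icer

params = default_parameters().replace(fh_detection_convention="paper_compat")
res = evaluate_all(params)
inc = icer(res["symptom_only"], res["fh_based"], params.wtp)
print(inc.icer, inc.classification)   # 185053.46899966875 cost_effective
```

Other subcommands: `dsa` (tornado table), `scenario` (bundled scenario
rows), `psa` (CE plane, CEAC and EVPI CSVs), `threshold`, `fixtures`.

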