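brca_test_1878:
  description: BRCA test cost cut 48% to the population-based break-even point
  overrides:
    cost_brca_test: 1878.0
brca_test_1808:
  description: BRCA test cost cut 50%
  overrides:
    cost_brca_test: 1808.0
p15_lifetime:
  description: lifetime (not to-age-70) ovarian-cancer risk in carriers
  overrides:
    p15: 0.202
p16_lifetime:
  description: lifetime breast-cancer risk in carriers
  overrides:
    p16: 0.644
lifetime_both:
  description: lifetime risks for both cancers
  overrides:
    p15: 0.202
    p16: 0.644
fh_rate_china:
  description: highest reported Chinese family-history positivity rate
  overrides:
    p50: 0.032
p1_us:
  description: US-level BRCA1/2 population prevalence
  overrides:
    p1: 0.00677
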