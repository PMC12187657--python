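p1: 0.003965
p15: 0.130385
p16: 0.374
p_BC_general: 0.036
p_OC_in_BRCAneg: 0.004
p_BC_in_BRCAneg: 0.034654
ratio_early_OC: 0.3
ratio_early_BC: 0.621
p20: 0.163
p26: 0.2115
p32: 0.2915
p38: 0.2585
rr_OC_RRA: 0.53
rr_BC_RRA: 0.64
rr_OC_RRM: 1.0
rr_BC_RRM: 0.114
rr_OC_RRSO: 0.21
rr_BC_RRSO: 0.49
rr_BC_RRM_RRSO: 0.05
p50: 0.0098
p51: 0.1
u_early_OC: 0.81
u_early_BC: 0.71
u_late_OC: 0.55
u_late_BC: 0.65
u_healthy: 1.0
u_RRM_y1: 0.88
u_RRSO_y1: 0.95
s_early_OC: 0.388
s_early_BC: 0.739
s_late_OC: 0.176
s_late_BC: 0.603
s_healthy: 0.977658738
cost_general_examination: 400.0
cost_periodical_examination: 1500.0
cost_FH_consel: 80.0
cost_brca_test: 3600.0
cost_rra: 536.0
cost_rrm: 5414.0
cost_rrso: 26881.0
cost_hrt: 4200.0
cost_diagnosis_cancer: 1600.0
horizon_years: 10.0
wtp: 268200.0
fh_detection_convention: coherent
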