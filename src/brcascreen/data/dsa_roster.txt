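p1
p15
p16
p_BC_general
p_OC_in_BRCAneg
p_BC_in_BRCAneg
ratio_early_OC
ratio_early_BC
p20
p26
p32
p38
rr_OC_RRA
rr_BC_RRA
rr_OC_RRM
rr_BC_RRM
rr_OC_RRSO
rr_BC_RRSO
rr_BC_RRM_RRSO
p50
p51
u_early_OC
u_early_BC
u_late_OC
u_late_BC
u_healthy
u_RRM_y1
u_RRSO_y1
s_early_OC
s_early_BC
s_late_OC
s_late_BC
s_healthy
cost_general_examination
cost_periodical_examination
cost_FH_consel
cost_brca_test
cost_rra
cost_rrm
cost_rrso
cost_hrt
cost_diagnosis_cancer
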