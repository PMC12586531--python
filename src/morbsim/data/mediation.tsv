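parameter	value	ci_low	ci_high
delta_sbp_per_bmi_unit	2.55	1.55	3.54
delta_tc_per_bmi_unit	0.23	0.15	0.30
bmi_floor	25.0
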