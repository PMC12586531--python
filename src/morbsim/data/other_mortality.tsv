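source	kind	form	rr_per_unit
sbp	exposure	log_linear_continuous	1.008
smoking	exposure	smoking_status	1.6
physical_activity	exposure	log_linear_continuous	1.04
chd	condition	categorical	1.6
stroke	condition	categorical	1.8
diabetes_type1	condition	categorical	1.6
diabetes_type2	condition	categorical	1.5
copd	condition	categorical	1.8
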