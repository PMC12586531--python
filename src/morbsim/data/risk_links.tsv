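exposure	condition	form	rr_per_unit	unit	lag_years	cumulative	affects_case_fatality	affects_nonmodelled_mortality
bmi	dementia	log_linear_continuous	1.05	kg/m2	5	0	1	0
smoking	dementia	smoking_status	1.8	cigarettes/day	5	0	1	1
physical_activity	breast_cancer	log_linear_continuous	1.06	days/week	9	0	1	1
bmi	breast_cancer	log_linear_continuous	1.04	kg/m2	9	0	1	0
smoking	breast_cancer	smoking_status	1.3	cigarettes/day	9	1	1	1
ets	breast_cancer	categorical	1.2	exposed	9	0	1	0
physical_activity	colorectal_cancer	log_linear_continuous	1.07	days/week	9	0	1	1
bmi	colorectal_cancer	log_linear_continuous	1.05	kg/m2	9	0	1	0
smoking	colorectal_cancer	smoking_status	1.4	cigarettes/day	9	1	1	1
smoking	lung_cancer	smoking_status	2.9	cigarettes/day	9	1	1	1
ets	lung_cancer	categorical	1.25	exposed	9	0	1	0
fruit	lung_cancer	log_linear_continuous	1.0009	g/day	9	0	1	0
smoking	prostate_cancer	smoking_status	1.3	cigarettes/day	9	0	1	1
smoking	copd	smoking_status	2.8	cigarettes/day	5	1	1	1
ets	copd	categorical	1.2	exposed	5	0	1	0
bmi	atrial_fibrillation	log_linear_continuous	1.05	kg/m2	5	0	1	0
smoking	atrial_fibrillation	smoking_status	1.4	cigarettes/day	5	0	1	1
sbp	atrial_fibrillation	log_linear_continuous	1.015	mmHg	4	0	1	1
physical_activity	stroke	log_linear_continuous	1.07	days/week	5	0	1	1
bmi	stroke	log_linear_continuous	1.04	kg/m2	5	0	1	0
smoking	stroke	smoking_status	1.8	cigarettes/day	5	0	1	1
ets	stroke	categorical	1.2	exposed	5	0	1	0
sbp	stroke	log_linear_continuous	1.025	mmHg	4	0	1	1
fruit	stroke	log_linear_continuous	1.0006	g/day	5	0	1	0
vegetables	stroke	log_linear_continuous	1.0006	g/day	5	0	1	0
total_cholesterol	stroke	log_linear_continuous	1.15	mmol/L	4	0	1	0
physical_activity	diabetes_type2	log_linear_continuous	1.1	days/week	5	0	1	1
bmi	diabetes_type2	log_linear_continuous	1.09	kg/m2	5	0	1	0
smoking	diabetes_type2	smoking_status	1.4	cigarettes/day	5	0	1	1
ets	diabetes_type2	categorical	1.15	exposed	5	0	1	0
sbp	diabetes_type2	log_linear_continuous	1.01	mmHg	4	0	1	1
fruit	diabetes_type2	log_linear_continuous	1.0005	g/day	5	0	1	0
bmi	ckd	log_linear_continuous	1.05	kg/m2	5	0	1	0
sbp	ckd	log_linear_continuous	1.02	mmHg	4	0	1	1
physical_activity	chd	log_linear_continuous	1.08	days/week	5	0	1	1
bmi	chd	log_linear_continuous	1.05	kg/m2	5	0	1	0
smoking	chd	smoking_status	1.9	cigarettes/day	5	0	1	1
ets	chd	categorical	1.2	exposed	5	0	1	0
sbp	chd	log_linear_continuous	1.02	mmHg	4	0	1	1
fruit	chd	log_linear_continuous	1.0007	g/day	5	0	1	0
vegetables	chd	log_linear_continuous	1.0006	g/day	5	0	1	0
total_cholesterol	chd	log_linear_continuous	1.3	mmol/L	4	0	1	0
bmi	asthma	log_linear_continuous	1.03	kg/m2	5	0	1	0
smoking	asthma	smoking_status	1.3	cigarettes/day	5	0	1	1
sbp	hypertension	log_linear_continuous	1.04	mmHg	4	0	1	1
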