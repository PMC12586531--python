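modelled_name	cms_condition	cms_weight	recovery_rule	can_recur	is_cancer	past_self_as_risk	past_self_rr	recovery_prob	has_parent_risks
dementia	dementia	2.50	none	0	0	0			1
breast_cancer	cancer	1.53	cancer_10yr	0	1	0			1
colorectal_cancer	cancer	1.53	cancer_10yr	0	1	0			1
lung_cancer	cancer	1.53	cancer_10yr	0	1	0			1
prostate_cancer	cancer	1.53	cancer_10yr	1	1	0			0
other_cancers	cancer	1.53	cancer_10yr	1	1	0			1
copd	copd	1.46	none	0	0	0			0
atrial_fibrillation	atrial_fibrillation	1.34	none	0	0	0			1
heart_failure	heart_failure	1.18	none	0	0	0			1
constipation	constipation	1.12	stochastic	1	0	1	2.0	0.30	1
epilepsy	epilepsy	0.92	none	0	0	0			1
chronic_pain	chronic_pain	0.92	stochastic	1	0	1	2.0	0.15	1
stroke	stroke_tia	0.80	none	0	0	0			1
diabetes_type1	diabetes	0.75	none	0	0	0			0
diabetes_type2	diabetes	0.75	none	0	0	0			0
alcohol_problems	alcohol_problems	0.65	stochastic	1	0	1	2.5	0.15	0
psychosis_bipolar	psychosis_bipolar	0.64	none	0	0	0			1
ckd	chronic_kidney_disease	0.53	none	0	0	0			0
anxiety_depression	anxiety_depression	0.50	stochastic	1	0	1	2.0	0.25	1
chd	coronary_heart_disease	0.49	none	0	0	0			1
rheumatoid_arthritis	connective_tissue	0.43	none	0	0	0			0
other_connective_tissue	connective_tissue	0.43	none	0	0	0			0
ibs	irritable_bowel_syndrome	0.21	none	0	0	0			0
asthma	asthma	0.19	stochastic	1	0	1	2.5	0.04	0
hearing_loss	hearing_loss	0.09	none	0	0	0			0
hypertension	hypertension	0.08	none	0	0	0			0
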