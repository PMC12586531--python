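condition	parent	rr
dementia	stroke	1.8
dementia	diabetes_type2	1.4
breast_cancer	diabetes_type2	1.2
colorectal_cancer	diabetes_type2	1.3
lung_cancer	copd	1.9
other_cancers	diabetes_type2	1.2
atrial_fibrillation	heart_failure	1.8
atrial_fibrillation	chd	1.5
atrial_fibrillation	hypertension	1.4
heart_failure	chd	2.2
heart_failure	hypertension	1.7
heart_failure	diabetes_type2	1.5
heart_failure	atrial_fibrillation	1.8
constipation	chronic_pain	1.5
epilepsy	stroke	2.5
chronic_pain	rheumatoid_arthritis	2.0
chronic_pain	anxiety_depression	1.5
stroke	atrial_fibrillation	2.5
stroke	diabetes_type2	1.5
stroke	chd	1.4
stroke	hypertension	1.6
psychosis_bipolar	anxiety_depression	1.6
anxiety_depression	chronic_pain	1.7
anxiety_depression	chd	1.3
chd	diabetes_type1	2.0
chd	diabetes_type2	1.8
chd	ckd	1.5
chd	hypertension	1.5
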