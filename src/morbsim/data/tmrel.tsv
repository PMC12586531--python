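exposure	central	unit	support_low	support_high	distribution
bmi	22.0	kg/m2	19.8	24.2	triangular
sbp	112.0	mmHg	100.8	123.2	triangular
total_cholesterol	4.0	mmol/L	3.6	4.4	triangular
fruit	320.0	g/day	288.0	352.0	triangular
vegetables	320.0	g/day	288.0	352.0	triangular
physical_activity	7.0	days/week	7.0	7.0	fixed
smoking	0.0	cigarettes/day	0.0	0.0	fixed
ets	0.0	exposed	0.0	0.0	fixed
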