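category	group	n_patients	pct
age	<18	13	0.1
age	18-29	279	2.9
age	30-39	631	6.6
age	40-49	1226	12.9
age	50-59	2230	23.4
age	60-69	2671	28
age	70-79	1850	19.4
age	80+	600	6.3
age	Not reported	23	0.2
gender	Female	5035	52.9
gender	Male	4488	47.1
ethnicity	Hispanic or Latino	343	3.6
ethnicity	Not Hispanic or Latino	6995	73.5
ethnicity	Not reported	2185	22.9
race	American Indian or Alaska Native	27	0.3
race	Asian	423	4.4
race	Black or African American	925	9.7
race	Native Hawaiian or Other Pacific Islander	13	0.1
race	Not reported	933	9.8
race	White	7202	75.6
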