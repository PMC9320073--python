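sample_id	who_grade	sex	age	idh1_2	loh_1p19q	tert
ID19	IV	M	67	wt	wt	wt
ID48	IV	M	72	wt	wt	wt
ID78	IV	F	67	wt	wt	wt
ID93	IV	M	62	wt	wt	wt
ID41	IV	F	45	wt	wt	wt
ID66	IV	M	47	wt	wt	wt
ID117	IV	F	56	wt	wt	wt
ID169	IV	M	52	wt	wt	c.-146C>T
ID121	IV	M	50	wt	wt	wt
ID143	IV	M	61	wt	wt	c.-124C>T
ID31	IV	M	75	wt	wt	wt
ID30	IV	F	76	wt	wt	wt
ID21	IV	F	54	wt	wt	wt
ID164	IV	F	63	wt	wt	wt
ID40	IV	F	76	wt	wt	wt
ID166	IV	F	73	wt	wt	wt
ID153	III	F	67	p.R132H	LOH	wt
ID209	IV	M	74	p.R132H	LOH	wt
ID232	II	F	48	p.R132H	LOH	wt
ID233	IV	M	42	p.R132H	LOH	wt
ID258	II	M	47	p.R132H	LOH	wt
ID260	IV	M	41	wt	LOH	wt
ID278	II	F	52	p.R132H	LOH	wt
ID49	IV	M	51	wt	wt	wt
ID79	IV	F	71	wt	wt	wt
ID38	IV	M	54	wt	wt	wt
ID192	IV	F	91	wt	wt	wt
ID199	IV	M	53	wt	wt	wt
ID176	IV	M	62	wt	wt	wt
ID104	IV	F	70	wt	wt	wt
ID09	IV	F	81	wt	1p	wt
ID10	IV	F	63	wt	19q	wt
ID85	IV	M	59	wt	19q	wt
IDsc21	IV	M	46	wt	1p	wt
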