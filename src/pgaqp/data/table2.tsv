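isoform	npa_lb	npa_le	arR_H2	arR_H5	arR_LE1	arR_LE2	froger_P1	froger_P2	froger_P3	froger_P4	froger_P5
PgPIP1-1	NPA	NPA	F	H	T	R	Q	S	A	F	W
PgPIP1-3	NPA	NPA	F	H	T	R	Q	S	A	F	W
PgPIP1-4	NPA	NPA	F	H	T	R	V	S	A	F	W
PgPIP2-1	NPA	NPA	F	H	T	R	Q	S	A	F	W
PgPIP2-2	NPA	NPA	F	H	T	R	Q	S	A	F	W
PgPIP2-3	NPA	NPA	F	H	T	R	Q	S	A	F	W
PgPIP2-5	NPA	NPA	F	H	T	R	-	S	A	F	W
PgPIP2-6	NPA	NPA	F	H	T	R	Q	S	A	F	W
PgPIP2-7	NPA	NPA	F	H	T	R	T	S	A	F	W
PgPIP2-8	NPA	NPA	F	H	T	R	H	S	A	F	W
PgTIP1-1	NPA	NPA	H	I	A	V	T	S	A	Y	W
PgTIP2-1	NPA	TPA	H	I	G	R	T	S	A	Y	W
PgTIP2-2	NPA	NPA	H	I	G	R	T	S	A	Y	W
PgTIP2-3	NPA	NPA	H	I	G	R	T	S	A	Y	W
PgTIP3-1	NPA	NPA	H	V	A	R	T	V	A	Y	W
PgTIP4-1	NPS	NPA	N	S	A	R	T	S	A	Y	W
PgTIP4-2	NPA	NPA	Q	S	A	R	T	S	A	Y	W
PgTIP4-3	NPA	NPA	H	I	A	H	T	S	A	Y	W
PgTIP5-1	NPA	NPA	Q	V	A	R	R	S	A	Y	W
PgNIP1-1	NPA	NPA	W	V	A	R	F	T	A	Y	V
PgNIP1-2	NPA	NPA	W	V	A	R	F	T	A	Y	F
PgNIP1-4	NPA	NPV	W	A	A	R	F	S	A	Y	I
PgNIP2-1	NPA	NPA	G	S	G	R	L	T	A	Y	F
PgNIP2-2	NPA	NPA	G	S	G	R	L	T	A	Y	F
PgNIP3-1	NPS	NPV	A	I	G	R	F	T	A	Y	L
PgNIP3-2	NPA	NPA	A	A	A	R	Y	T	A	Y	M
PgNIP3-3	NPA	NPA	A	A	A	R	Y	T	A	Y	M
PgNIP3-4	NPA	NPA	A	A	A	R	Y	T	A	Y	M
PgNIP3-5	NPA	NPA	A	A	A	R	Y	T	A	Y	M
PgNIP4-1	NPA	NPI	M	G	G	R	M	T	A	Y	L
PgSIP1-1	NPT	NPA	V	V	P	N	M	A	A	Y	W
PgSIP1-2	NPT	NPA	L	I	P	N	M	A	A	Y	W
PgSIP2-1	NPL	NPA	S	H	G	S	F	A	A	Y	W
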