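maturity_group	e1la_genotype	e_background	n	dtf	dtm
MG I	REF	e1-as e2 E3	2	35.5	110.5
MG I	e1la:K82E	e1-as e2 E3	6	33.7	98.5
MG II	REF	e1-as E2 e3	1	38.0	115.0
MG II	e1la:K82E	e1-as E2 e3	3	34.7	105.3
MG III	REF	e1-as E2 E3	2	47.0	126.0
MG III	e1la:K82E	e1-as E2 E3	10	39.1	115.6
MG V	REF	E1 E2 E3	2	63.0	140.0
MG V	e1la:K82E	E1 E2 E3	2	59.0	132.0
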