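variable	level	Healthy	SLE	CFS	ADCLS
sex	Male	4	0	4	3
sex	Female	21	11	21	10
ethnicity	Aboriginal	0	0	2	0
ethnicity	White	20	5	23	13
ethnicity	Chinese	3	3	0	0
ethnicity	Other	2	3	0	0
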