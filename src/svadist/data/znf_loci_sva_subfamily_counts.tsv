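locus	subfamily	count
chr19:53,000,001-54,000,000	A	1
chr19:53,000,001-54,000,000	D	4
chr19:53,000,001-54,000,000	E	3
chr4:1-1,000,000	D	3
chr4:1-1,000,000	E	2
chr4:1-1,000,000	F	1
chr7:64,000,001-65,000,000	B	1
chr7:64,000,001-65,000,000	C	2
chr7:64,000,001-65,000,000	D	5
chr7:64,000,001-65,000,000	E	1
chr7:64,000,001-65,000,000	F	2
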