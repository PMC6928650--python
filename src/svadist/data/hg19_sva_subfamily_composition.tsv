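subfamily	genome_share_pct
A	7.82
B	16.45
C	10.17
D	44.39
E	4.94
F	13.43
F1	2.80
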