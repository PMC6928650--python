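chr19	20000000	24000000	both	41	.
chr19	53000000	54000000	young	8	.
chr4	0	1000000	young	6	.
chr7	63000000	65000000	young	12	.
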