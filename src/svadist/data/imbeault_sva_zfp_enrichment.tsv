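protein	position	sva_locus	sva_a	sva_b	sva_c	sva_d	sva_e	sva_f
ZNF141	chr4:331,596-367,691	Y	7.76e-6	4.53e-89	1.04e-62	5.07e-5	0.13	0.40
ZNF736	chr7:63,773,186-63,810,017	Y	0.61	1.00	0.53	3.13e-14	3.98e-4	1.24e-23
ZNF257	chr19:22,235,266-22,273,903	Y	4.43e-83	4.11e-10	4.85e-4	2.11e-6	0.19	4.9e-5
ZNF730	chr19:23,299,777-23,330,017	Y	1.00	1.00	0.17	2.97e-27	6.05e-7	3.99e-42
ZNF611	chr19:53,206,066-53,238,307	Y	1.14e-320	1.14e-320	1.14e-320	1.14e-320	7.8e-200	1.14e-320
ZNF28	chr19:53,300,661-53,324,922	Y	1.09e-67	1.09e-22	4.62e-25	2.5e-234	3.37e-4	3.2e-110
ZKSCAN5	chr7:99,102,273-99,131,445	N	2.93e-13	9.43e-5	8.21e-3	2.6e-39	2.77e-31	1.92e-74
ZNF202	chr11:123,594,997-123,612,363	N	0.91	0.88	0.73	2.52e-12	2.04e-13	7.67e-57
ZNF641	chr12:48,733,793-48,744,674	N	0.01	1.71e-5	3.79e-13	2.7e-201	4.1e-104	2.4e-304
ZNF605	chr12:133,498,019-133,532,892	N	7.96e-3	0.07	0.04	7.83e-58	1.03e-23	4.68e-67
ZNF558	chr19:8,920,382-8,933,565	N	0.05	1.00	1.69e-4	8.94e-57	1.55e-30	6.4e-135
ZNF30	chr19:35,417,807-35,436,076	N	1.00	0.14	2.22e-4	2.56e-63	5.32e-28	2.5e-134
ZNF780A	chr19:40,578,899-40,596,845	N	0.25	3.70e-3	1.79e-3	1.14e-26	0.02	2.59e-14
ZNF649	chr19:52,392,488-52,408,305	N	1.87e-3	0.06	7.23e-6	6.1e-158	9.68e-66	3.9e-191
ZNF334	chr20:45,128,269-45,142,198	N	1.00	0.05	1.00	2.1e-12	2.91e-17	2.14e-21
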