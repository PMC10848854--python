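amino_acid	codon	count	rscu_published
Phe	UUU	254	1.69
Phe	UUC	47	0.31
Leu	UUA	83	1.06
Leu	UUG	189	2.42
Leu	CUU	66	0.84
Leu	CUC	21	0.27
Leu	CUA	39	0.50
Leu	CUG	71	0.91
Ile	AUU	191	1.65
Ile	AUC	40	0.35
Met	AUA	63	0.57
Met	AUG	159	1.43
Val	GUU	151	1.52
Val	GUC	48	0.48
Val	GUA	69	0.69
Val	GUG	130	1.31
Ser	UCU	90	1.97
Ser	UCC	21	0.46
Ser	UCA	29	0.63
Ser	UCG	43	0.94
Ser	AGU	27	0.59
Ser	AGC	20	0.44
Ser	AGA	73	1.60
Ser	AGG	63	1.38
Pro	CCU	65	1.70
Pro	CCC	26	0.68
Pro	CCA	28	0.73
Pro	CCG	34	0.89
Thr	ACU	70	1.74
Thr	ACC	27	0.67
Thr	ACA	28	0.70
Thr	ACG	36	0.89
Ala	GCU	101	1.54
Ala	GCC	47	0.71
Ala	GCA	47	0.71
Ala	GCG	68	1.03
Gly	GGU	73	0.83
Gly	GGC	47	0.53
Gly	GGA	82	0.93
Gly	GGG	151	1.71
Arg	CGU	35	1.26
Arg	CGC	20	0.72
Arg	CGA	30	1.08
Arg	CGG	26	0.94
Tyr	UAU	136	1.50
Tyr	UAC	45	0.50
His	CAU	47	1.08
His	CAC	40	0.92
Gln	CAA	22	0.80
Gln	CAG	33	1.20
Asn	AAU	77	1.43
Asn	AAC	31	0.57
Lys	AAA	86	0.98
Lys	AAG	89	1.02
Asp	GAU	75	1.61
Asp	GAC	18	0.39
Glu	GAA	57	0.77
Glu	GAG	92	1.23
Cys	UGU	64	1.28
Cys	UGC	36	0.72
Trp	UGA	62	0.73
Trp	UGG	107	1.27
*	UAA	3	0.55
*	UAG	8	1.45
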