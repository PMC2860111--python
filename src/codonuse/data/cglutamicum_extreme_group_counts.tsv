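aa	codon	n_high	rscu_high	n_low	rscu_low
Phe	UUU	149	0.17	1058	1.37
Phe	UUC	1608	1.83	481	0.63
Leu	UUA	19	0.03	486	0.78
Leu	UUG	239	0.33	1284	2.06
Leu	CUU	656	0.91	707	1.13
Leu	CUC	1583	2.21	341	0.55
Leu	CUA	140	0.20	274	0.44
Leu	CUG	1666	2.32	651	1.04
Ile	AUU	412	0.43	1207	1.71
Ile	AUC	2477	2.57	654	0.93
Ile	AUA	7	0.01	257	0.36
Met	AUG	1143	1.00	863	1.00
Val	GUU	1495	1.45	883	1.11
Val	GUC	1631	1.59	452	0.57
Val	GUA	336	0.33	396	0.50
Val	GUG	650	0.63	1443	1.82
Tyr	UAU	47	0.07	632	1.41
Tyr	UAC	1311	1.93	262	0.59
TER	UAA	100	2.19	39	0.85
TER	UAG	33	0.72	51	1.12
His	CAU	47	0.09	560	1.35
His	CAC	981	1.91	271	0.65
Gln	CAA	284	0.34	539	0.79
Gln	CAG	1385	1.66	830	1.21
Asn	AAU	141	0.13	795	1.37
Asn	AAC	1955	1.87	369	0.63
Lys	AAA	298	0.26	664	0.91
Lys	AAG	2014	1.74	800	1.09
Asp	GAU	959	0.55	1537	1.53
Asp	GAC	2559	1.45	468	0.47
Glu	GAA	2117	1.04	1095	0.91
Glu	GAG	1941	0.96	1313	1.09
Ser	UCU	371	0.77	539	1.22
Ser	UCC	1972	4.11	284	0.64
Ser	UCA	175	0.36	360	0.82
Ser	UCG	59	0.12	676	1.53
Pro	CCU	527	0.92	492	1.11
Pro	CCC	185	0.32	205	0.46
Pro	CCA	1454	2.55	371	0.84
Pro	CCG	119	0.21	705	1.59
Thr	ACU	304	0.38	605	1.20
Thr	ACC	2758	3.45	427	0.85
Thr	ACA	74	0.09	378	0.75
Thr	ACG	61	0.08	601	1.20
Ala	GCU	1707	1.18	957	1.08
Ala	GCC	1138	0.79	512	0.58
Ala	GCA	2529	1.75	789	0.89
Ala	GCG	411	0.28	1300	1.46
Cys	UGU	64	0.44	213	1.30
Cys	UGC	230	1.56	114	0.70
TER	UGA	4	0.09	47	1.03
Trp	UGG	577	1.00	661	1.00
Arg	CGU	744	1.62	557	1.45
Arg	CGC	1887	4.11	362	0.94
Arg	CGA	89	0.19	317	0.83
Arg	CGG	16	0.03	489	1.27
Ser	AGU	19	0.04	483	1.09
Ser	AGC	284	0.59	305	0.69
Arg	AGA	5	0.01	236	0.62
Arg	AGG	13	0.03	341	0.89
Gly	GGU	1026	0.93	1069	1.46
Gly	GGC	2830	2.55	562	0.77
Gly	GGA	549	0.50	568	0.78
Gly	GGG	26	0.02	724	0.99
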