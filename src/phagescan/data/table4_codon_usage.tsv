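family	codon	spp1_fraction	spp1_count	bs_fraction	bs_count	divergent_printed
Ala	GCG	0.26	268	0.26	24574	no
Ala	GCA	0.27	272	0.28	26416	no
Ala	GCU	0.27	279	0.25	23062	no
Ala	GCC	0.20	201	0.21	19342	no
Arg	AGG	0.18	130	0.10	4788	no
Arg	AGA	0.28	198	0.26	13077	no
Arg	CGG	0.12	83	0.15	7329	no
Arg	CGA	0.10	74	0.11	5115	no
Arg	CGU	0.18	125	0.18	8755	no
Arg	CGC	0.14	99	0.20	9444	no
Asn	AAU	0.45	344	0.57	27137	yes
Asn	AAC	0.55	425	0.43	20861	yes
Asp	GAU	0.52	442	0.64	40291	yes
Asp	GAC	0.48	415	0.36	22699	yes
Cys	UGU	0.54	50	0.45	4429	no
Cys	UGC	0.46	42	0.55	5322	no
Gln	CAG	0.38	192	0.46	22750	no
Gln	CAA	0.62	319	0.54	23889	no
Glu	GAG	0.39	452	0.32	28211	no
Glu	GAA	0.61	704	0.68	59808	no
Gly	GGG	0.21	215	0.16	13670	no
Gly	GGA	0.31	318	0.31	26381	no
Gly	GGU	0.24	245	0.18	15457	no
Gly	GGC	0.25	262	0.34	28493	no
His	CAU	0.53	131	0.67	18610	yes
His	CAC	0.47	119	0.33	9019	yes
Ile	AUA	0.27	261	0.13	11517	yes
Ile	AUU	0.35	335	0.50	45181	yes
Ile	AUC	0.38	365	0.37	32872	no
Leu	UUG	0.24	246	0.16	18745	no
Leu	UUA	0.24	251	0.20	23338	no
Leu	CUG	0.10	107	0.24	28295	yes
Leu	CUA	0.13	139	0.05	6030	no
Leu	CUU	0.20	203	0.24	28226	no
Leu	CUC	0.08	87	0.11	13232	no
Lys	AAG	0.38	460	0.30	25647	no
Lys	AAA	0.62	760	0.70	60072	no
Met	AUG	1.00	412	1.00	32918	no
Phe	UUU	0.48	270	0.68	37445	yes
Phe	UUC	0.52	294	0.32	17253	yes
Pro	CCG	0.44	219	0.43	19421	no
Pro	CCA	0.26	127	0.19	8541	no
Pro	CCU	0.22	107	0.29	12824	no
Pro	CCC	0.08	42	0.09	4001	no
Ser	AGU	0.16	123	0.11	8096	no
Ser	AGC	0.22	170	0.23	17226	no
Ser	UCG	0.10	79	0.10	7717	no
Ser	UCA	0.25	193	0.24	18053	no
Ser	UCU	0.17	132	0.20	15615	no
Ser	UCC	0.11	83	0.13	9757	no
Thr	ACG	0.26	211	0.27	17693	no
Thr	ACA	0.47	379	0.41	27117	no
Thr	ACU	0.15	120	0.16	10620	no
Thr	ACC	0.12	94	0.16	10497	no
Trp	UGG	1.00	190	1.00	12571	no
Tyr	UAU	0.50	276	0.65	27650	yes
Tyr	UAC	0.50	278	0.35	14673	yes
Val	GUG	0.23	211	0.26	21585	no
Val	GUA	0.26	240	0.20	16296	no
Val	GUU	0.32	292	0.28	23440	no
Val	GUC	0.18	168	0.26	21143	no
End	UGA	0.39	31	0.24	965	yes
End	UAG	0.11	9	0.14	591	no
End	UAA	0.50	40	0.62	2542	yes
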