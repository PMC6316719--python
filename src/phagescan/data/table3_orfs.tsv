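orf	rbs_mrna	spacing	start_codon	start_nt	stop_codon	stop_nt	length_aa	mm_kda	essential	tmm	note
1	AAGGAGGU	10	AUG	43884	UGA	311	147	16.3	yes	no
2			AUG	308	UAG	1576	422	48.8	yes	1	no_rbs
3	AAAGGAGG	11	AUG	1567	UAA	1782	71	8.5	no	no
4	GGgGGU	10	AUG	1782	UAA	2072	96	11.4	no	no
5	AAGGAGG	11	AUG	2065	UGA	2334	89	10.3	no	no
6	AGGAGGU	11	AUG	2336	UGA	3847	503	57.3	yes	no
7	AGGAGG	12	AUG	3804	UAA	4730	308	35.1	no	no
8	AAAGGAG	12	AUG	5067	UGA	6215	382	43.7	n.d.	no
9	AAcGGAGG	9	AUG	6217	UAA	6555	112	12.6	n.d.	no
10	GGuGGUG	12	AUG	6583	UAG	6750	55	6.2	n.d.	no	flexible_spacing
11	AGGAG	9	AUG	6917	UAA	7561	214	23.4	yes	no
12	AAGGgGG	11	AUG	7576	UAA	7770	64	6.6	no	no
13	AAAGGAG	9	AUG	7803	UAA	8777	324	35.3	yes	no
14	AAAGGAG	10	AUG	8828	UGA	9004	58	6.7	no	no
15	AAuGAGG	10	AUG	9015	UAA	9323	102	11.6	yes	no
16			AUG	9325	UAG	9654	109	12.5	yes	no	no_rbs
16.1	AAaGAGG	11	AUG	9644	UGA	10069	141	15.9	n.d.	no
17	AGGAGGU	10	AUG	10066	UGA	10470	134	15	yes	no
17.1	AGGAGG	10	AUG	10484	UAA	11017	177	19.2	yes	no
17.1*	AGGAGG	10	AUG	10484	UAA	11279	264	28.2	no	no	plus1_frameshift
17.5	GAGG	12	AUG	11363	UAA	11884	173	20.2	n.d.	no
17.5*	GAGG	12	AUG	11363	UAG	12255	297	34	n.d.	no	minus1_frameshift
18	AGGAGG	9	AUG	12267	UGA	15365	1032	110.9	n.d.	4
19.1	GAGG	10	AUG	15362	UAA	16123	253	28.6	n.d.	no
21	AAGaAGGUGA	10	UUG	16137	UAA	19463	1108	123.6	n.d.	no
22	AAGGAGG	9	AUG	19476	UAA	19916	146	16.7	n.d.	no
23	AGGAGGU	10	AUG	19932	UGA	20096	54	6.1	n.d.	no
23.1	GGAG	9	AUG	20089	UAA	20244	51	5.8	n.d.	no
24	GgGGUG	10	AUG	20237	UAG	20467	76	8.4	n.d.	no	flexible_spacing
24.1	AAAGGgGG	11	AUG	20547	UAA	20825	92	10.6	n.d.	1
24.1*	AGGAGGU	10	AUG	20574	UAA	20825	83	9.5	n.d.	1	dual_start
25	AAGGAG	12	AUG	20845	UAA	21660	271	29.9	n.d.	no
26	AAAGGAG	8	AUG	21662	UAA	21910	82	9.4	n.d.	2
26*	AAAGGAG	14	AUG	21668	UAA	21910	80	9.1	n.d.	2	dual_start
26.1	AAGGgGG	10	AUG	22009	UAG	22152	47	5.8	n.d.	no
27	AAGGAGG	12	UUG	22277	UAA	22831	184	20.8	n.d.	no
28	GGAGG	9	AUG	22834	UGA	23121	95	10.8	n.d.	no
29	AGGAGG	13	AUG	23069	UGA	23371	100	12	n.d.	no
29.1	AGGgGG	9	GUG	23358	UGA	23675	105	12.3	n.d.	no
30	AGGgGG	10	AUG	23675	UAA	23854	59	7.2	n.d.	1
30.1	AGGgGG	9	AUG	23859	UGA	24029	56	6.4	n.d.	no
31	AAcGGAGGU	12	AUG	24209	UAA	24493	94	11	n.d.	no
31.1	GAGG	12	AUG	24589	UAA	24951	120	12.9	n.d.	3
31.2	GgGGUG	10	AUG	24964	UGA	25281	105	11.5	no	2	flexible_spacing
32	GGAGGUG	8	AUG	25278	UAA	27788	836	96.3	no	no
32.5	GGAGGUG	11	UUG	28039	UAA	28209	56	6.7	n.d.	no
33	AAAaGgGGU	11	AUG	28226	UAA	29995	589	64.9	no	no
33.1	AAcGGAGG	9	AUG	30011	UAA	30229	72	8.4	n.d.	no
34	AGGgGG	9	AUG	30364	UAG	30522	52	6.3	n.d.	no
34.1	AGGAGG	9	AUG	30534	UGA	31469	311	35.9	no	no
34.2	GGAGG	12	AUG	31466	UAA	31639	57	6.7	n.d.	no
34.3	AAGGAGG	11	AUG	31641	UAA	31895	84	9.8	n.d.	no
34.4	GGAGG	11	AUG	31897	UAA	32187	96	11.1	n.d.	no
35	GGAGGU	11	AUG	32177	UAG	33040	287	32	yes	no
36	AGGAGGgGA	10	AUG	33033	UAA	33512	159	17.1	no	no
36.1	AAaGgGGUGA	10	AUG	33537	UGA	34028	163	18.9	n.d.	no	flexible_spacing
37	GGAGG	10	AUG	34032	UGA	34406	124	14.3	n.d.	no
37.1	GGAGG	11	AUG	34399	UGA	34992	197	22.3	n.d.	no
37.2	GaAGG	14	AUG	34989	UGA	35243	84	9.7	n.d.	no
37.3	AGGAGG	11	AUG	35400	UAG	35573	57	6.7	n.d.	no
38	AAGGAGG	13	AUG	35580	UGA	36350	256	30	yes	no
39	AGGAGG	9	AUG	36347	UGA	36727	126	14.6	yes	no
40	GAGG	11	AUG	36724	UAA	38052	442	49.7	yes	no
41	AAAGGgGG	10	AUG	38069	UGA	38569	166	19.1	n.d.	no
42	AAAGGAG	11	AUG	38566	UAA	38961	131	16	no	no
42.1	GGAGG	9	AUG	38964	UGA	39134	56	6.5	no	no
42.2	GgGG	12	AUG	39131	UAA	39427	98	10.7	no	no	weak_rbs
43	GGAGG	10	GUG	39431	UGA	39784	117	14.2	no	no
44	AAGGAG	11	AUG	39777	UAA	40487	236	27.5	no	no
46	GAGG	12	AUG	40596	UAA	40898	100	11.5	no	no
46.1	AGGAGG	9	AUG	40898	UAA	41209	103	11.7	no	3
47	AGGgGG	9	AUG	41304	UGA	41663	119	13.7	no	no
48	GGAG	13	AUG	41645	UGA	41995	116	13.2	no	no
49	GGAGG	9	GUG	42075	UGA	42248	57	6.5	no	no
50	AAGGAGG	9	GUG	42245	UAA	42418	57	6.8	no	no
50.1	AAAGGAGG	9	GUG	42434	UGA	42616	60	6.7	no	2
51	AAGGAGG	9	AUG	42613	UAA	43014	133	14.7	no	1
51.1	AAGGAG	9	AUG	43027	UGA	43182	51	6.1	no	1
52	AAAGGAG	10	AUG	43179	UGA	43421	80	9.5	no	no
53	AAAGGAG	10	AUG	43405	UGA	43611	68	7.4	no	1
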