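gene	site	position_printed	aa_index	nt_index_printed	codon_before	codon_after	aa_before_printed	aa_after_printed	coverage	count_ref	count_alt	printed_pct_ref	printed_pct_alt	synonymous_flag_printed
rbcL	1	50/150	50	150	CCC	CCU	P	P	188389	39	187680	0.02	99.62	1
matK	1	160/478	160	478	CAU	UAU	H	Y	751	195	556	26.1	73.9	0
matK	2	245/734	245	734	UCU	UUU	S	F	3612	1888	1718	52.3	47.6	0
psbA	1	232/696	232	696	UCC	UCU	S	S	2011054	387	2002141	0.02	99.56	1
atpA	1	258/774	258	774	UCA	UUA	S	L	2684	37	2646	1.4	98.5	0
atpA	2	383/1148	383	1148	UCA	UUA	S	L	3878	51	3821	1.3	98.5	0
atpF	1	31/92	31	92	CCA	CUA	P	L	3913	331	3579	8.5	91.4	0
atpI	1	15/45	15	45	UAC	UAU	Y	Y	3682	2736	940	74.3	25.5	0
atpI	2	210/629	210	629	UCA	UUA	S	L	3580	47	3528	1.3	98.5	0
rpoC2	1	1235/3704	1235	3704	UCA	UUA	S	L	493	43	451	8.7	91.3	0
rpoC1	1	14/41	14	41	CCA	CUA	P	L	764	203	558	26.5	72.9	0
rpoC1	2	61/182	61	182	UCC	UUC	S	F	1004	543	462	54	46	0
rpoC1	3	107/321	107	321	AUC	AUU	I	I	818	487	331	59.5	40.4	1
rpoC1	4	178/500	178	500	UCA	UUA	S	L	848	98	750	11.5	88.3	0
rpoC1	5	210/629	210	629	UCA	UUA	S	L	857	149	709	17.4	82.6	0
rpoC1	6	267/799	267	799	CGG	UGG	R	W	906	43	859	4.7	94.7	0
rpoB	1	29-10	29	10	UCC	UUC	S	F	223	81	142	36.2	63.4	0
rpoB	2	113/338	113	338	UCU	UUU	S	F	205	82	123	39.8	59.7	0
rpoB	3	184/551	184	551	UCA	UUA	S	F	78	66	13	83.5	16.5	0
rpoB	4	189/566	189	566	UCA	UUA	S	F	112	54	59	47.8	52.2	0
rpoB	5	665/1994	665	1994	UCA	UUU	S	F	233	11	223	4.7	95.3	0
rpoB	6	807/2420	807	2420	UCA	UUA	S	F	230	31	200	13.4	86.6	0
rpoB	7	900/2698	900	2698	CCU	UCU	P	S	286	75	212	26.1	73.9	0
psbZ	1	17/50	17	50	UCA	UUA	S	L	23558	869	22664	3.7	96.2	0
psbZ	2	60/180	60	180	CUC	CUU	L	L	15389	14560	810	94.6	5.3	1
rps14	1	27/80	27	80	UCA	UUA	S	L	14988	470	14472	3.1	96.6	0
psaA	1	51/153	51	153	GCC	GCU	A	A	10434	6	10407	0.1	99.7	1
ycf3	1	15/44	15	44	UCU	UUU	S	F	2070	694	1372	33.5	66.2	0
ycf3	2	21/63	21	63	AUC	AUU	I	I	1477	640	834	43.3	56.4	1
ycf3	3	62/185	62	185	ACG	AUG	T	M	648	502	146	77.3	22.5	0
ycf3	4	64/191	64	191	CCA	CUA	P	L	903	423	469	46.8	51.9	0
ndhJ	1	43/128	43	128	UCA	UUA	S	L	968	245	724	25.3	74.7	0
ndhK	1	23/69	23	69	CCC	CCU	P	P	264	155	110	58.5	41.5	1
ndhK	2	27/81	27	81	UUC	UUU	F	F	343	191	153	55.5	44.5	1
ndhC	1	13-5	13	5	CAC	UAC	H	Y	335	69	267	20.5	79.5	0
ndhC	2	104/311	104	311	CCA	CUA	P	L	264	155	110	58.5	41.5	0
ndhC	3	108/323	108	323	UCA	UUA	S	L	343	191	153	55.5	44.5	0
atpB	1	395/1184	395	1184	UCA	UUA	S	L	8704	140	8556	1.6	98.3	0
accD	1	452/1355	452	1355	UCA	UUA	S	L	625	224	393	35.8	62.8	0
accD	2	466/1397	466	1397	UCC	UUC	P	L	574	245	329	42.6	57.2	0
psaI	1	25/74	25	74	UCU	UUU	S	F	1721	579	1140	33.6	66.2	0
psaI	2	27/80	27	80	CAU	UAU	H	Y	1152	1078	72	93.5	6.2	0
psaI	3	34/102	34	102	GUC	GUU	V	V	3243	2758	482	85	14.9	0
ycf4	1	176/528	176	528	UUC	UUU	F	F	2311	1774	538	76.7	23.3	1
psbJ	1	20/59	20	59	CCU	CUU	P	L	21133	392	20673	1.9	97.8	0
psbF	1	26/77	26	77	UCU	UUU	S	F	8436	252	8177	3	96.9	0
psbE	1	72/214	72	214	CCU	UCU	P	S	13182	145	13023	1.1	98.8	0
petL	1	2/5	2	5	UCU	UUU	S	F	2646	559	2084	21.1	78.7	0
petL	2	19/56	19	56	CCA	CUA	P	L	1591	48	1540	3	96.7	0
rps18	1	74/221	74	221	UCG	UUG	S	L	5264	283	4975	5.4	94.5	0
clpP	1	26/82	26	82	CAU	UAU	H	Y	865	110	756	12.7	87.3	0
clpP	2	187/559	187	559	CAU	UAU	H	Y	1533	107	1402	5.4	91.4	0
psbN	1	10/30	10	30	UUC	UUU	F	F	57622	12298	45238	21.3	78.5	1
petB	1	4/11	4	11	AAU	AGU	N	S	10646	8356	2268	78.5	21.3	0
petB	2	142/424	142	424	CGG	UGG	R	W	27257	290	26917	1.1	98.7	0
petB	3	206/617	206	617	CCA	CUA	P	L	9585	220	9351	2.3	97.5	0
petD	1	162/484	162	484	CAA	UAA	Q	*	13552	248	13286	1.8	98	0
rpoA	1	67/200	67	200	UCU	UUU	S	F	947	323	622	34.1	65.6	0
rpoA	2	123/368	123	368	UCA	UUA	S	L	1193	254	938	21.3	78.6	0
rpl36	1	14-5	14	5	GUU	GCU	V	A	3479	2	3475	0.1	99.8	0
rps3	1	157/470	157	470	ACA	AUA	T	I	1513	74	1440	4.9	95.1	0
rps3	2	195/583	195	583	CAU	UAU	H	Y	1951	309	1638	15.8	83.9	0
rpl2	1	1/2	1	2	ACG	AUG	T	M	708	340	369	48	52	0
rpl23	1	24/71	24	71	UCU	UUU	S	F	562	84	479	48	85.1	0
ndhB	1	50/149	50	149	UCA	UUA	S	L	803	88	716	10.9	89.1	0
ndhB	2	156/467	156	467	CCA	CUA	P	L	929	41	887	4.4	95.4	0
ndhB	3	181/542	181	542	ACG	AUG	T	M	536	55	482	10.2	89.8	0
ndhB	4	204/611	204	611	UCA	UUA	S	L	343	58	286	16.9	83.1	0
ndhB	5	205/704	205	704	UCC	UUC	S	F	347	53	295	15.2	84.8	0
ndhB	6	246/737	246	737	CCA	CUA	P	L	167	65	102	38.7	60.7	0
ndhB	7	277/830	277	830	UCA	UUA	S	L	193	123	71	61.3	36.4	0
ndhB	8	279/836	279	836	UCA	UUA	S	L	162	80	83	49.1	50.9	0
ndhB	9	371/112	371	112	UCA	UUA	S	L	1134	108	1025	9.5	90.3	0
ndhB	10	494/1481	494	1481	CCA	CUA	P	L	1271	188	1082	14.8	85.1	0
ndhF	1	21/62	21	62	UCA	UUA	S	L	674	46	628	6.8	93	0
ndhF	2	87/259	87	259	CAC	UAC	H	Y	208	51	158	24.4	75.6	0
ndhF	3	131/392	131	392	UCU	UUU	S	F	1205	13	1191	11.1	98.8	0
ccsA	1	118/353	118	353	UCA	UUA	S	L	750	70	680	9.3	90.5	0
ccsA	2	272/815	272	815	UCA	UUA	S	L	731	68	662	9.3	90.4	0
ndhD	1	1/2	1	2	ACG	AUG	T	M	791	285	505	36	63.8	0
ndhD	2	22/65	22	65	UCC	UUC	S	F	628	82	545	13	86.6	0
ndhD	3	130/389	130	389	UCA	UUA	S	L	722	129	593	17.8	82	0
ndhD	4	227/680	227	680	UCG	UUG	S	L	840	190	648	22.6	77.1	0
ndhD	5	318/953	318	953	ACA	AUA	T	I	930	124	803	13.3	86.3	0
ndhG	1	17/50	17	50	UCA	UUA	S	L	531	115	417	21.6	78.4	0
ndhG	2	116/347	116	347	CCG	CUG	P	L	1198	107	1088	8.9	90.7	0
ndhA	1	358/1073	358	1073	UCC	UUC	S	F	1467	198	1226	13.5	86.2	0
ndhH	1	30-10	30	10	CUC	CUU	L	L	1107	1020	85	92.1	7.7	1
ndhH	2	169/505	169	505	CAU	UAU	H	Y	740	85	651	11.5	87.9	0
rrn5S	1	-/72	-	72	C	U	-	-	9350	24	9258	0.3	99	0
rrn23S	1	-/1327	-	1327	U	C	-	-	2532	2148	381	84.8	15	0
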