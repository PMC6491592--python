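gene	length_bp	rpkm
psbA	1032	557101
rbcL	1443	72754
petB	1467	11128
psbC	1416	9863
petD	1233	9292
psbH	222	8993
psbD	1062	8199
psbZ	189	6822
psaC	246	6521
psbB	1527	5815
psbN	132	5486
psbE	252	5439
rps14	303	5273
psaA	2253	4791
psaB	2205	4244
psbJ	123	3913
atpB	1497	3584
rpl33	204	3280
atpE	408	3191
atpH	246	2600
psbL	117	2587
psaJ	129	2369
psbK	192	2181
rps18	306	2058
atpA	1524	1966
rps16	1142	1964
matK	1539	1865
atpI	744	1798
psbF	120	1780
atpF	1338	1766
ycf4	555	1700
cemA	709	1460
rps11	417	1391
petA	963	1363
ndhE	306	1341
ycf3	1949	1259
rpl14	369	1235
rpl16	1420	1158
rps8	399	1052
infA	228	1042
ndhA	2080	1004
psbT	102	932
psbI	111	837
ndhJ	477	827
rps3	657	788
rpoA	1008	705
ndhI	540	680
ndhF	2229	641
rpl32	174	626
rps7	468	622
petG	114	555
rps19	279	523
rpl22	393	496
clpP	1991	488
ndhK	872	459
ndhG	534	454
rpoC1	2837	451
ndhB	2215	425
ndhD	1506	411
accD	1470	400
rps4	606	382
rps15	273	369
ndhH	1182	365
ccsA	966	362
rps12	914	360
rpl36	114	338
rpl2	1497	310
rps2	711	303
ndhC	363	292
rpl23	282	220
ycf1	5577	207
psaI	105	190
rpl20	354	177
rpoC2	4125	171
rpoB	3207	133
psbM	105	112
petN	90	89
ycf2	6621	70
ycf15	231	56
petL	960	13
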