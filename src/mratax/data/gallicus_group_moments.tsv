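otu	sex	n	character	min	max	mean	sd
biglumis	female	19	cly.b	1286	1586	1453.4	84.23
biglumis	female	19	eye.d	1540	1880	1704.2	98.79
biglumis	female	19	eye.h	2033	2500	2268.4	131.22
biglumis	female	19	flgfirst.l	829	1000	932.3	48.06
biglumis	female	19	flglast.b	286	343	315	15.95
biglumis	female	19	flglast.l	300	393	334.6	22.75
biglumis	female	19	hea.b	2933	3500	3238.6	175.07
biglumis	female	19	hea.h	2600	3033	2805.3	136.2
biglumis	female	19	lof.l	1580	1920	1751.6	94.83
biglumis	female	19	msp.l	371	514	445.5	34.85
biglumis	female	19	ool.l	514	629	578.6	31.59
biglumis	female	19	pol.l	264	379	325.2	33.53
biglumis	female	19	scp.b	379	486	444	28.3
biglumis	female	19	scp.l	1157	1400	1281.2	71.75
biglumis	female	19	tib3.b	507	650	585	40.05
biglumis	female	19	tib3.l	2900	3767	3387.7	250.73
biglumis	male	20	cly.b	1157	1371	1241.4	52.62
biglumis	male	20	eye.d	1480	1760	1602	65.82
biglumis	male	20	eye.h	2067	2433	2280	80.5
biglumis	male	20	flgfirst.l	1000	1129	1081.4	37.11
biglumis	male	20	flglast.b	157	186	172.9	9.15
biglumis	male	20	flglast.l	293	421	364.3	37.08
biglumis	male	20	hea.b	3067	3533	3261.7	98.1
biglumis	male	20	hea.h	2467	2833	2643.3	75.78
biglumis	male	20	lof.l	1540	1840	1695	59.78
biglumis	male	20	msp.l	371	436	403.6	22.53
biglumis	male	20	ool.l	471	571	529.3	29.03
biglumis	male	20	pol.l	279	386	326.4	22.72
biglumis	male	20	scp.b	450	564	512.1	26.74
biglumis	male	20	scp.l	1129	1314	1202.1	49.55
biglumis	male	20	tib3.b	521	614	577.9	29.3
biglumis	male	20	tib3.l	3000	3733	3428.3	163.04
bischoffi	female	46	cly.b	1057	1386	1216.5	90.3
bischoffi	female	46	eye.d	1300	1640	1453.9	80.76
bischoffi	female	46	eye.h	1833	2333	2069.6	135.32
bischoffi	female	46	flgfirst.l	671	886	781.1	53.03
bischoffi	female	46	flglast.b	257	314	286.5	14.85
bischoffi	female	46	flglast.l	279	386	320.2	18.83
bischoffi	female	46	hea.b	2533	3167	2842	163.52
bischoffi	female	46	hea.h	2167	2767	2447.8	152.45
bischoffi	female	46	lof.l	1340	1720	1516.1	102.99
bischoffi	female	46	msp.l	250	350	289.4	22.57
bischoffi	female	46	ool.l	429	529	472.8	26.92
bischoffi	female	46	pol.l	264	357	321.9	21.63
bischoffi	female	46	scp.b	314	414	365.1	27.32
bischoffi	female	46	scp.l	986	1271	1113.7	70.5
bischoffi	female	46	tib3.b	393	600	486	46.19
bischoffi	female	46	tib3.l	2600	3633	3072.5	256.69
bischoffi	male	13	cly.b	943	1100	983.5	44.74
bischoffi	male	13	eye.d	1280	1480	1352.3	57.47
bischoffi	male	13	eye.h	1900	2167	2056.4	87.54
bischoffi	male	13	flgfirst.l	871	1000	944	30.56
bischoffi	male	13	flglast.b	150	171	158.2	7.05
bischoffi	male	13	flglast.l	400	471	425.3	23.26
bischoffi	male	13	hea.b	2667	3033	2864.1	100.43
bischoffi	male	13	hea.h	2167	2433	2305.1	81.47
bischoffi	male	13	lof.l	1460	1620	1520	48.99
bischoffi	male	13	msp.l	171	207	187.4	10.97
bischoffi	male	13	ool.l	379	479	417	28.35
bischoffi	male	13	pol.l	293	364	319.8	20.24
bischoffi	male	13	scp.b	379	450	416.5	20.07
bischoffi	male	13	scp.l	943	1100	1041.8	46.46
bischoffi	male	13	tib3.b	429	500	470.9	24.99
bischoffi	male	13	tib3.l	2767	3233	3061.5	156.26
gallicus	female	42	cly.b	1143	1471	1290.5	74.11
gallicus	female	42	eye.d	1420	1720	1560.5	73.58
gallicus	female	42	eye.h	1900	2533	2134.1	125.26
gallicus	female	42	flgfirst.l	714	929	795.6	46.85
gallicus	female	42	flglast.b	271	336	303.2	14.13
gallicus	female	42	flglast.l	286	357	313.6	18.92
gallicus	female	42	hea.b	2733	3400	3017.5	149.3
gallicus	female	42	hea.h	2333	2900	2556.3	134.24
gallicus	female	42	lof.l	1420	1820	1583.8	89.14
gallicus	female	42	msp.l	293	393	333.3	24.93
gallicus	female	42	ool.l	457	571	512.4	32.02
gallicus	female	42	pol.l	279	371	333.3	21.32
gallicus	female	42	scp.b	343	436	383.7	22.1
gallicus	female	42	scp.l	1057	1343	1172.4	61.21
gallicus	female	42	tib3.b	471	607	525.7	37.5
gallicus	female	42	tib3.l	2767	3733	3211.9	236.94
gallicus	male	25	cly.b	900	1186	1026.3	59.29
gallicus	male	25	eye.d	1200	1560	1419.2	75.38
gallicus	male	25	eye.h	1833	2267	2064	118.21
gallicus	male	25	flgfirst.l	886	1114	975.4	48.36
gallicus	male	25	flglast.b	136	179	160.6	12.39
gallicus	male	25	flglast.l	329	457	385.4	33.02
gallicus	male	25	hea.b	2633	3233	2921.3	149.96
gallicus	male	25	hea.h	2167	2733	2401.3	122.66
gallicus	male	25	lof.l	1420	1820	1575.2	87.99
gallicus	male	25	msp.l	186	307	243.1	27.85
gallicus	male	25	ool.l	357	521	450.3	28.31
gallicus	male	25	pol.l	271	371	308.9	27.53
gallicus	male	25	scp.b	379	471	428	22.77
gallicus	male	25	scp.l	914	1171	1054.3	62.13
gallicus	male	25	tib3.b	436	600	493.1	37.6
gallicus	male	25	tib3.l	2600	4000	3212	269.92
hellenicus	female	21	cly.b	1171	1457	1313.6	87.19
hellenicus	female	21	eye.d	1440	1720	1568.6	92.43
hellenicus	female	21	eye.h	2000	2400	2188.9	143.89
hellenicus	female	21	flgfirst.l	743	929	831.3	51.63
hellenicus	female	21	flglast.b	279	336	299	15.2
hellenicus	female	21	flglast.l	271	371	314.3	27.94
hellenicus	female	21	hea.b	2767	3300	3036.5	172.85
hellenicus	female	21	hea.h	2367	2867	2603.2	158.43
hellenicus	female	21	lof.l	1460	1820	1613.3	113.37
hellenicus	female	21	msp.l	279	400	341.5	34
hellenicus	female	21	ool.l	457	564	517.7	32.62
hellenicus	female	21	pol.l	271	357	322.8	20.78
hellenicus	female	21	scp.b	364	436	396.9	18.98
hellenicus	female	21	scp.l	1086	1286	1181	72.19
hellenicus	female	21	tib3.b	500	614	544.6	32.25
hellenicus	female	21	tib3.l	3033	3767	3360.3	246.45
hellenicus	male	9	cly.b	957	1057	1014.3	34.99
hellenicus	male	9	eye.d	1280	1540	1422.2	98.71
hellenicus	male	9	eye.h	1933	2200	2055.6	92.8
hellenicus	male	9	flgfirst.l	871	986	941.3	40.05
hellenicus	male	9	flglast.b	143	171	155.6	8.58
hellenicus	male	9	flglast.l	364	414	391.3	18.48
hellenicus	male	9	hea.b	2600	2967	2837	112.35
hellenicus	male	9	hea.h	2200	2467	2377.8	83.33
hellenicus	male	9	lof.l	1460	1640	1566.7	58.31
hellenicus	male	9	msp.l	179	257	219	22.87
hellenicus	male	9	ool.l	414	514	462.7	30.88
hellenicus	male	9	pol.l	286	336	302.4	20.52
hellenicus	male	9	scp.b	379	443	420.6	22.99
hellenicus	male	9	scp.l	957	1100	1042.9	40.41
hellenicus	male	9	tib3.b	464	521	496	20.55
hellenicus	male	9	tib3.l	3033	3333	3225.9	124.47
helveticus	female	34	cly.b	1071	1457	1254.2	83.36
helveticus	female	34	eye.d	1420	1780	1538.8	79.99
helveticus	female	34	eye.h	1800	2333	2045.1	129.2
helveticus	female	34	flgfirst.l	657	871	780.7	49.47
helveticus	female	34	flglast.b	264	321	295	16.82
helveticus	female	34	flglast.l	300	407	327.9	23.81
helveticus	female	34	hea.b	2567	3233	2866.7	155.27
helveticus	female	34	hea.h	2267	2833	2521.6	147
helveticus	female	34	lof.l	1380	1780	1552.4	100.79
helveticus	female	34	msp.l	293	429	357.4	29.92
helveticus	female	34	ool.l	450	607	515.1	28.07
helveticus	female	34	pol.l	293	414	348.3	27.75
helveticus	female	34	scp.b	343	457	387.6	31.52
helveticus	female	34	scp.l	1000	1300	1129.8	70.63
helveticus	female	34	tib3.b	421	600	506.1	48.06
helveticus	female	34	tib3.l	2667	3567	3049	223.27
helveticus	male	27	cly.b	914	1057	994.2	37.64
helveticus	male	27	eye.d	1280	1600	1425.2	71.6
helveticus	male	27	eye.h	1800	2133	1998.8	82.42
helveticus	male	27	flgfirst.l	857	986	928	33.03
helveticus	male	27	flglast.b	129	193	161.6	12.07
helveticus	male	27	flglast.l	279	457	346.8	37.76
helveticus	male	27	hea.b	2633	3033	2893.8	90.13
helveticus	male	27	hea.h	2133	2467	2355.6	71.61
helveticus	male	27	lof.l	1400	1620	1547.4	54.95
helveticus	male	27	msp.l	214	293	249.5	20.2
helveticus	male	27	ool.l	386	536	450	31.13
helveticus	male	27	pol.l	279	379	328.6	24.82
helveticus	male	27	scp.b	386	464	430.2	16.38
helveticus	male	27	scp.l	943	1086	1028	33.26
helveticus	male	27	tib3.b	429	536	487.3	27.83
helveticus	male	27	tib3.l	2800	3300	3080.2	142.1
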