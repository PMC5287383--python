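no	observed_mz	adduct	composition	control_mean	control_sd	model_mean	model_sd	treated_mean	treated_sd	sig_vs_control	sig_vs_model
1	933.33	[M+Na]+	(Hex)3(HexNAc)2			7.04	12.19
2	996.75	[M+2Na]2+	(Hex)5(HexNAc)4(Neu5Gc)1			28.90	26.32	37.75	4.03
3	1095.33	[M+Na]+	(Hex)4(HexNAc)2	6.30	10.90	15.68	5.48	6.86	11.87
4	1136.42	[M+Na]+	(Hex)3(HexNAc)3			23.96	3.30	26.46	3.28
5	1150.67	[M+2Na]2+	(Hex)5(HexNAc)4(Neu5Gc)2	17.44	17.09	16.10	14.21	29.05	6.92
6	1153.17	[M+2Na]2+	(Hex)4(HexNAc)5(Neu5Ac)2	61.19	17.03	26.26	23.47	40.84	1.76
7	1176.17	[M+2Na]2+	(Hex)3(HexNAc)6(Fuc)2(NeuAc)1	38.48	34.46
8	1257.42	[M+Na]+	(Hex)5(HexNAc)2	46.49	8.79	46.27	8.77	56.65	5.40
9	1298.42	[M+Na]+	(Hex)4(HexNAc)3	49.74	15.62	45.20	7.87	50.10	4.63
10	1339.33	[M+Na]+	(Hex)3(HexNAc)4			5.28	9.15
11	1419.33	[M+Na]+	(Hex)6(HexNAc)2	31.77	27.61	45.25	6.72	56.32	3.73
12	1460.17	[M+Na]+	(Hex)5(HexNAc)3	45.45	12.42	19.22	18.88	34.72	0.70
13	1485.42	[M+Na]+	(Hex)3(HexNAc)4(Fuc)1	81.39	20.23	38.55	34.08	64.20	7.39
14	1501.42	[M+Na]+	(Hex)4(HexNAc)4			17.91	15.90
15	1518.17	[M+H]+	(Hex)8(HexNAc)1	55.06	16.90	26.38	10.08	21.88	18.97
16	1565.08	[M+Na]+	(Hex)6(HexNAc)2(Fuc)1	6.02	10.42	3.72	6.44	3.69	6.40
17	1581.42	[M+Na]+	(Hex)7(HexNAc)2			13.04	2.49	10.44	9.04
18	1605.25	[M+Na]+	(Hex)4(HexNAc)3(Neu5Gc)1	24.90	8.64	18.99	5.91	22.95	2.36
19	1622.42	[M+Na]+	(Hex)6(HexNAc)3			4.86	8.41
20	1647.5	[M+Na]+	(Hex)4(HexNAc)4(Fuc)1	96.53	22.57	64.58	20.94	83.08	5.96
21	1663.33	[M+Na]+	(Hex)5(HexNAc)4	59.67	52.99	83.38	15.36	90.29	7.08
22	1679.33	[M+K]+	(Hex)5(HexNAc)4	8.47	7.69	10.21	8.86	15.71	1.67
23	1727.17	[M+Na]+	(Hex)7(HexNAc)2(Fuc)1	15.11	13.22	7.45	6.73	11.26	1.17
24	1743.58	[M+Na]+	(Hex)8(HexNAc)2	4.47	7.75	11.86	1.94	14.03	0.28
25	1767.25	[M+Na]+	(Hex)5(HexNAc)3(Neu5Gc)1	25.39	8.54	15.53	5.70	18.03	0.88
26	1783.25	[M+K]+	(Hex)5(HexNAc)3(Neu5Gc)1	5.60	9.69
27	1809.5	[M+Na]+	(Hex)5(HexNAc)4(Fuc)1	39.45	11.40	26.14	6.94	20.95	18.16
28	1825.25	[M+Na]+	(Hex)5(HexNAc)4(Fuc)1	39.23	11.05	20.37	7.72	24.47	1.78	*
29	1885.33	[M+H]+	(Hex)4(HexNAc)6	22.17	6.13	10.78	4.56	13.77	0.50
30	1905.58	[M+Na]+	(Hex)8(HexNAc)2	8.91	8.47	7.33	6.39	4.80	8.32
31	1970.33	[M+Na]+	(Hex)5(HexNAc)4(Neu5Gc)1	67.45	27.07	62.19	20.73	70.39	11.18
32	1986.33	[M+K]+	(Hex)5(HexNAc)4(Neu5Gc)1	152.52	56.67	72.77	39.77	90.35	1.85
33	951.25	[M-H]-	(Hex)2(HexNAc)3	4.96	0.93	1.23	2.12	3.54	1.15
34	1075.67	[M-4H+2Na]2-	(Hex)3(HexNAc)6(Neu5Gc)1S1	8.43	9.42	10.04	2.54	6.31	5.47
35	1126.17	[M-2H]2-	(Hex)5(HexNAc)4(Neu5Gc)2	41.86	19.00	26.77	9.13	32.75	7.60
36	1154.33	[M-H]-	(Hex)2(HexNAc)4	7.43	1.09	4.75	0.85	6.99	0.30	*	#
37	1199.67	[M-2H]2-	(Hex)5(HexNAc)4(Fuc)1(Neu5Gc)2	7.04	2.27	2.80	2.42	3.27	2.83
38	1234.33	[M-H]-	(Hex)5(HexNAc)2			1.22	2.11	3.21	2.78
39	1258.08	[M-H]-	(Hex)3(HexNAc)3(Fuc)1	14.94	5.64	7.02	1.15	9.37	4.52	*
40	1309.17	[M-2H]2-	(Hex)6(HexNAc)5(Neu5Gc)2	40.73	23.56			25.63	16.28
41	1316.25	[M-H]-	(Hex)3(HexNAc)4	10.93	2.93	5.63	4.89	5.74	4.97
42	1401.17	[M-2H]2-	(Hex)5(HexNAc)4(Neu5Ac)4	15.02	5.23	6.11	5.34	7.88	7.23
43	1420.17	[M-H]-	(Hex)4(HexNAc)3(Fuc)1			3.68	6.37	12.46	2.49
44	1462.67	[M-2H]2-	(Hex)6(HexNAc)5(Neu5Gc)3	13.58	6.66	4.83	4.23	4.95	4.29
45	1497.25	[M-2H+Na]-	(Hex)2(HexNAc)2(Fuc)1(Neu5Ac)2	2.93	5.07
46	1559.25	[M-H]-	(Hex)2(HexNAc)6	7.98	7.02	2.91	5.03
47	1581.33	[M-H]-	(Hex)4(HexNAc)3(Neu5Gc)1	17.66	8.88	18.33	2.48	20.61	0.87
48	1659.42	[M-2H+Na]-	(Hex)3(HexNAc)2(Fuc)1(Neu5Ac)2	3.08	5.34
49	1721.25	[M-H]-	(Hex)3(HexNAc)6	12.27	2.89	5.12	4.82	9.86	1.00
50	1743.5	[M-H]-	(Hex)5(HexNAc)3(Neu5Gc)1	18.29	4.14	14.35	2.89	15.31	0.23
51	1784.33	[M-H]-	(Hex)4(HexNAc)4(Neu5Gc)1	22.81	21.09	25.56	5.60	26.36	0.82
52	1823.08	[M-2H+Na]-	(Hex)3(HexNAc)6S1	12.27	4.66	13.93	0.74	8.54	7.40
53	1845.17	[M-3H+2Na]-	(Hex)3(HexNAc)6S1	15.59	14.82	15.11	2.77	17.33	4.83
54	1905.5	[M-H]-	(Hex)6(HexNAc)3(Neu5Gc)1	18.15	3.62	11.89	2.23	14.37	0.77	*
55	1946.5	[M-H]-	(Hex)5(HexNAc)4(Neu5Gc)1	109.10	42.94	95.91	23.40	112.52	8.99
56	1968	[M-2H+Na]-	(Hex)5(HexNAc)4(Neu5Gc)1	2.78	4.82	6.09	0.46	4.34	3.76
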