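no	observed_mz	adduct	composition	control_mean	control_sd	model_mean	model_sd	treated_mean	treated_sd	sig_vs_control	sig_vs_model
1	1013.25	[M+Na]+	(Hex)6	7.65	13.24			16.26	14.09
2	1079.33	[M+Na]+	(Hex)3(HexNAc)2(Fuc)1	10.88	18.84			10.95	18.97
3	1095.33	[M+Na]+	(Hex)4(HexNAc)2					4.86	8.42
4	1136.42	[M+Na]+	(Hex)3(HexNAc)3			12.99	22.49	10.11	17.52
5	1175.33	[M+Na]+	(Hex)7					7.30	12.65
6	1257.42	[M+Na]+	(Hex)5(HexNAc)2	127.72	56.63	74.41	17.89	146.88	47.49
7	1273.25	[M+K]+	(Hex)5(HexNAc)2	25.72	22.29			29.15	13.14
8	1298.42	[M+Na]+	(Hex)4(HexNAc)3	11.09	19.20	11.36	19.68
9	1337.33	[M+Na]+	(Hex)8					14.68	14.15
10	1339.33	[M+Na]+	(Hex)3(HexNAc)4	10.14	17.56			4.29	7.44
11	1419.33	[M+Na]+	(Hex)6(HexNAc)2	50.61	18.67	14.22	24.64	54.64	20.40
12	1435.42	[M+K]+	(Hex)6(HexNAc)2					10.38	17.99
13	1444.50	[M+Na]+	(Hex)4(HexNAc)3(Fuc)1			13.88	24.04
14	1460.17	[M+Na]+	(Hex)5(HexNAc)3					4.15	7.18
15	1485.42	[M+Na]+	(Hex)3(HexNAc)4(Fuc)1	32.70	5.87	12.04	20.86	6.77	11.73
16	1501.42	[M+Na]+	(Hex)4(HexNAc)4			11.04	19.12
17	1581.42	[M+Na]+	(Hex)7(HexNAc)2	28.42	7.76	9.34	16.18	28.58	9.66
18	1647.50	[M+Na]+	(Hex)4(HexNAc)4(Fuc)1	17.51	15.50	9.83	17.03	7.33	12.69
19	1663.33	[M+Na]+	(Hex)5(HexNAc)4	8.06	13.97			7.89	13.67
20	1688.50	[M+Na]+	(Hex)3(HexNAc)5(Fuc)1	30.02	6.34	23.39	20.31	16.62	16.84
21	1743.58	[M+Na]+	(Hex)8(HexNAc)2	21.40	20.30			22.37	19.43
22	1809.50	[M+Na]+	(Hex)5(HexNAc)4(Fuc)1					3.56	6.16
23	1905.58	[M+Na]+	(Hex)8(HexNAc)2	18.10	15.90	8.17	14.15	21.80	7.98
24	1931.25	[M+H]+	(Hex)5(HexNAc)4(Neu5Ac)1	7.13	12.35	7.13	12.35
25	951.25	[M-H]-	(Hex)2(HexNAc)3	24.89	21.74
26	1031.25	[M-H]-	(Hex)5(HexNAc)1	12.25	21.23	74.61	98.09	14.80	25.64
27	1072.25	[M-H]-	(Hex)4(HexNAc)2	94.92	19.20	39.98	35.23	106.49	33.32
28	1126.17	[M-2H]2-	(Hex)5(HexNAc)4(Neu5Gc)2	43.35	5.17	31.62	27.55	66.33	34.43
29	1154.33	[M-H]-	(Hex)2(HexNAc)4	32.17	28.32			25.84	44.75
30	1193.25	[M-H]-	(Hex)6(HexNAc)1			46.49	80.53
31	1234.33	[M-H]-	(Hex)5(HexNAc)2					38.34	35.22
32	1331.25	[M-H]-	(Hex)2(HexNAc)2(Fuc)2(Neu5Ac)1	99.76	15.50	49.15	49.66	100.26	54.13
33	1396.33	[M-H]-	(Hex)6(HexNAc)2					51.89	7.59
34	1420.17	[M-H]-	(Hex)4(HexNAc)3(Fuc)1			12.29	21.28	17.07	29.57
35	1475.17	[M-H]-	(Hex)2(HexNAc)2(Fuc)1(Neu5Ac)2	52.37	5.96	14.01	24.27	33.73	30.02
36	1493.25	[M-H]-	(Hex)3(HexNAc)2(Fuc)2(Neu5Ac)1	19.85	34.37	44.43	6.95	72.83	27.07
37	1559.25	[M-H]-	(Hex)2(HexNAc)6	62.39	4.18	32.95	30.02	29.41	50.93
38	1655.08	[M-H]-	(Hex)4(HexNAc)2(Fuc)2(Neu5Ac)1	61.86	6.32	24.18	21.17	40.48	39.45
39	1721.25	[M-H]-	(Hex)3(HexNAc)6	26.91	23.32	19.03	18.33	18.57	32.17
40	1762.25	[M-H]-	(Hex)2(HexNAc)7	56.02	4.75	36.83	3.67	29.76	26.05	**
41	1817.08	[M-H]-	(Hex)5(HexNAc)2(Fuc)2(Neu5Ac)1	61.43	3.91	35.11	7.83	57.42	20.29	**
42	1905.50	[M-H]-	(Hex)6(HexNAc)3(Neu5Gc)1	11.22	19.43
43	1979.33	[M-2H+Na]-	(Hex)3(HexNAc)5(Fuc)1(Neu5Ac)1	69.68	7.52	33.75	2.30	60.87	20.82	**	#
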