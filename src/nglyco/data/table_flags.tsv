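table	row	flag	detail
cortex	21	duplicate-species	(Hex)8(HexNAc)2 [M+Na]+ also appears as row 23 at a different printed mass
cortex	23	mass-inconsistent	printed m/z 1905.58 is ~162 Da above theoretical 1743.58 for (Hex)8(HexNAc)2; consistent with one additional Hex
cortex	43	mass-inconsistent	printed m/z 1979.33 deviates ~1.6 Da from theoretical ~1977.69 for (Hex)3(HexNAc)5(Fuc)1(Neu5Ac)1 [M-2H+Na]-
serum	24	duplicate-species	(Hex)8(HexNAc)2 [M+Na]+ also appears as row 30 at a different printed mass
serum	30	mass-inconsistent	printed m/z 1905.58 is ~162 Da above theoretical 1743.58 for (Hex)8(HexNAc)2; consistent with one additional Hex
serum	27	duplicate-species	(Hex)5(HexNAc)4(Fuc)1 [M+Na]+ also appears as row 28 at a different printed mass
serum	28	mass-inconsistent	printed m/z 1825.25 is ~15.75 Da above theoretical 1809.50 for (Hex)5(HexNAc)4(Fuc)1 [M+Na]+
serum	46	count-discrepancy	detectable in the model group and undetectable under treatment, so the stated rules call it treatment-suppressed, yet the narrative inhibited list omits it (modulated-by-treatment 6 narrative vs 7 rule-derived)
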