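# Anaerobic butane oxidation (AOB) pathway, oxidative direction.
# Standard transformed Gibbs energies (kJ/mol) at pH 7, 298 K; gas-phase butane and CO2.
# dg0_a/dg0_b give dG0' = dg0_a*Ex + dg0_b for steps whose energy depends on the
# standard redox potential Ex (V) of the unknown syntrophic electron carrier X/XH2.
# table_version: 1
index	name	enzyme	equation	multiplicity	dg0_const	dg0_a	dg0_b
1	butane activation	ACR	C4H10 + CoM-S-S-CoB = C4H9-S-CoM + HS-CoB	1	16.900
2	heterodisulfide recycling	Hdr-FrhB	HS-CoM + HS-CoB + 2 Fd_red + 2 H+ + 2 F420 = CoM-S-S-CoB + 2 Fd_ox + 2 F420H2	1	7.141
3	butyl-CoM to butyryl-CoA	unknown	C4H9-S-CoM + CoA + H2O + 2 X = Butyryl-CoA + HS-CoM + 2 XH2	1		-386	-55.801
4	butyryl-CoA oxidation	Bcd-Etf	Butyryl-CoA + 2 NAD+ + 2 Fd_red = Crotonyl-CoA + 2 NADH + 2 Fd_ox	1	25.090
5	crotonyl-CoA hydration	Ech	Crotonyl-CoA + H2O = 3-Hydroxybutyryl-CoA	1	0.300
6	hydroxybutyryl-CoA oxidation	HADH	3-Hydroxybutyryl-CoA + NAD+ = Acetoacetyl-CoA + NADH + H+	1	12.545
7	thiolytic cleavage	ACAT	Acetoacetyl-CoA + CoA = 2 Acetyl-CoA	1	-28.100
8	NADH oxidation	NDH	NADH + H+ + MQ = NAD+ + MQH2	5	-46.320
9	acetyl-CoA cleavage	ACS-CODH	Acetyl-CoA + H4MPT + 2 Fd_ox + H2O = CH3-H4MPT + CoA + CO2 + 2 Fd_red + 2 H+	2	66.114
10	methyl-H4MPT oxidation	Met	CH3-H4MPT + NAD+ = CH2-H4MPT + NADH + H+	2	1.140
11	methylene-H4MPT oxidation	Mtd	CH2-H4MPT + F420 + H+ = CH-H4MPT+ + F420H2	2	-6.500
12	methenyl-H4MPT hydration	Mch	CH-H4MPT+ + H2O = CHO-H4MPT + H+	2	2.000
13	formyl transfer	Ftr	CHO-H4MPT + MF = CHO-MF + H4MPT	2	-21.100
14	formyl-MF oxidation	Fwd	CHO-MF + H2O + 2 Fd_ox = CO2 + MF + 2 H+ + 2 Fd_red	2	0.598
15	F420H2 oxidation	Fqo	F420H2 + MQ = F420 + MQH2	4	-50.180
16	ferredoxin oxidation	Nuo	2 Fd_red + 2 H+ + MQ = 2 Fd_ox + MQH2	2	-81.060
17	terminal electron transfer	MHCs	MQH2 + X = MQ + XH2	11		-193	-15.440
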