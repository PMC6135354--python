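accession	gene	protein_name	peptides	mean_group0	mean_group1	fc	direction	p_st	p_si
P51781	GSTA1	Glutathione S-transferase A1	5	-0.41	0.54	0.52	group1	0.077	0.026
I3LVE1	KHK	Ketohexokinase	3	-0.24	0.64	0.54	group1	0.005	0.027
I3LEI5	CES3	Carboxylesterase 3	2	-0.64	0.23	0.55	group1	0.006	0.014
B1A8Z3	PYGL	Glycogen phosphorylase, liver form	5	-0.45	0.38	0.56	group1	0.022	0.036
Q9TV69	DHDH	Trans-1,2-dihydrobenzene-1,2-diol dehydrogenase	3	-0.39	0.30	0.62	group1	0.091	0.016
A0A286ZKH3	SPR	Sepiapterin reductase	5	-0.41	0.19	0.66	group1	0.042	0.044
A0A286ZIW5	ILVBL	Acetolactate synthase-like protein	2	-0.21	0.34	0.68	group1	0.031	0.027
F1RII7	HBB	Hemoglobin subunit beta	8	-0.20	0.33	0.69	group1	0.080	0.042
F1RQP0	PRDX5	Peroxiredoxin-5, mitochondrial	8	-0.20	0.31	0.70	group1	0.042	0.024
F1SLX5	AASS	Alpha-aminoadipic semialdehyde synthase, mitochondrial	2	-0.42	-0.02	0.76	group1	0.073	0.029
A5YV76	FASN	Fatty acid synthase	7	-0.12	0.17	0.82	group1	0.086	0.035
F1SSS0	CPS1	Carbamoyl-phosphate synthase [ammonia], mitochondrial	39	0.12	-0.07	1.14	group0	0.084	0.066
F1RKG8	PEBP1	Phosphatidylethanolamine-binding protein 1	7	0.21	-0.24	1.37	group0	0.073	0.038
D0G0B3	ACAA2	3-ketoacyl-CoA thiolase, mitochondrial	10	0.36	-0.20	1.48	group0	0.010	0.016
F1S2X3	ECHDC1	Ethylmalonyl-CoA decarboxylase	2	0.09	-0.49	1.50	group0	0.086	0.041
F1S0C1	ADH5	Alcohol dehydrogenase class-3	4	0.38	-0.24	1.53	group0	0.068	0.052
F1RMH5	UROC1	Urocanate hydratase	3	0.25	-0.41	1.58	group0	0.029	0.035
I3LP02	ACAT1	Acetyl-CoA acetyltransferase, mitochondrial	2	0.22	-0.57	1.73	group0	0.099	0.023
F1RL81	HSD17B14	17-beta-hydroxysteroid dehydrogenase 14	4	0.29	-0.51	1.74	group0	0.047	0.026
A0A287AR55	FH	Fumarate hydratase, mitochondrial	3	0.40	-0.43	1.78	group0	0.059	0.044
F1RWY0	RGN	Regucalcin	9	0.40	-0.45	1.80	group0	0.051	0.055
F2Z558	YWHAZ	14-3-3 protein zeta/delta	2	0.33	-0.64	1.96	group0	0.082	0.048
UPI0002105648	HIST2H2BF	Histone H2B type 2-F	2	0.58	-0.40	1.97	group0	0.009	0.008
F1RIF3	FAH	Fumarylacetoacetase	3	0.54	-0.48	2.02	group0	0.005	0.052
I3LDY2	LOC100625049	Uncharacterized protein	3	0.54	-0.85	2.63	group0	0.012	0.020
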