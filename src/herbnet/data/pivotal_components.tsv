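Mol ID	Molecule name	DL	AlogP	OB (%)	HL
MOL000497	Licochalcone A	0.29	4.62	40.79	16.2
MOL000098	Quercetin	0.28	1.5	46.43	14.4
MOL000006	Luteolin	0.25	2.07	36.16	15.94
MOL000422	Kaempferol	0.24	1.77	41.88	14.74
MOL000173	Wogonin	0.23	2.59	30.68	17.75
MOL002928	Oroxylin A	0.23	2.59	41.37	17.15
MOL000392	Formononetin	0.21	2.58	69.67	17.04
MOL004328	Naringenin	0.21	2.3	59.29	16.98
MOL002714	Baicalein	0.21	2.33	33.52	16.25
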