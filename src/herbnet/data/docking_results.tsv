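Active ingredients	Hub genes	kcal/mol	Total interactions
Licochalcone A	STAT3	−6.5	11
Licochalcone A	MAPK1	−7.2	14
Quercetin	JUN	−5.4	9
Quercetin	MAPK1	−7.4	9
Quercetin	CDK1	−9.1	12
Quercetin	HSPB1	−8.9	7
Luteolin	JUN	−5.6	8
Luteolin	PCNA	−7	8
Luteolin	MAPK1	−7.5	6
Kaempferol	JUN	−5.1	5
Kaempferol	CDK1	−8.2	8
Wogonin	JUN	−5.7	7
Oroxylin A	CDK1	−8.1	7
Formononetin	JUN	−5.3	6
Naringenin	MAPK1	−7	7
Baicalein	CDK1	−8.3	4
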