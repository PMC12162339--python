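accession	gene_symbol	protein_name	domains	family_side
Q8NEV9	IL27	p28	-	ligand
Q14213	EBI3	EBI3	PF00041.26	ligand
P29459	IL12A	p35	PF03039.19	ligand
P29460	IL12B	p40	PF10420.14	ligand
Q9NPF7	IL23A	p19	PF16649.10	ligand
Q5VWK5	IL23R	IL-23R	-	receptor
Q6UWB1	IL27RA	WSX-1	-	receptor
P42701	IL12RB1	IL-12Rβ1	PF00041.26	receptor
Q99665	IL12RB2	IL-12Rβ2	PF00041.26;PF06328.16	receptor
P40189	IL6ST	gp130	PF00041.26;PF06328.16;PF09240.15	receptor
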