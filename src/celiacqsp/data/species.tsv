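name	initial_value	compartment	description
Glut_lum	0.0	lumen	gluten peptides in the intestinal lumen
Glut_lam	0.0	lamina	native gluten peptides in the lamina propria
dGlut	0.0	lamina	deamidated gluten peptides (incl. TG-2 complexes)
Zon	0.0	lumen	zonulin
IEC	1.0	epithelium	mature intestinal epithelial cells
aIEC	0.0	epithelium	activated IECs
IEL	10.0	epithelium	intraepithelial lymphocytes
aIEL	0.0	epithelium	activated IELs (natural killers)
IL15	0.0	lamina	interleukin-15
IF21	0.0	lamina	merged IFN-gamma + IL-21 pool
APC	0.001	lamina	DQ2/DQ8 antigen-presenting cells
aAPC	0.0	lamina	activated APCs
T	5.0	lamina	T cells (merged Th1 + Th17)
aTt	0.0	lamina	transient activated-T compartment
aT	0.0	lamina	activated T cells
Ab	0.0	plasma	antibodies to gluten peptides and TG-2
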