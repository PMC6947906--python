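block_kind	residue	weight
qn_prionlike	Q	0.26
qn_prionlike	N	0.26
qn_prionlike	S	0.12
qn_prionlike	G	0.10
qn_prionlike	Y	0.14
qn_prionlike	T	0.05
qn_prionlike	K	0.03
qn_prionlike	R	0.04
charged_disordered	E	0.20
charged_disordered	D	0.15
charged_disordered	K	0.18
charged_disordered	R	0.12
charged_disordered	S	0.12
charged_disordered	G	0.10
charged_disordered	P	0.07
charged_disordered	T	0.04
charged_disordered	Y	0.02
hydrophobic_ordered	I	0.20
hydrophobic_ordered	L	0.22
hydrophobic_ordered	V	0.18
hydrophobic_ordered	F	0.14
hydrophobic_ordered	A	0.16
hydrophobic_ordered	M	0.06
hydrophobic_ordered	W	0.04
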