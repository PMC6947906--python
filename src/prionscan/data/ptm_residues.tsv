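ptm_type	residues
serine-phosphorylation	S
threonine-phosphorylation	T
tyrosine-phosphorylation	Y
lysine-acetylation	K
lysine-methylation	K
lysine-ubiquitination	K
lysine-sumoylation	K
arginine-methylation	R
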