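# Class I pMHC immunogenicity model: per-residue log-enrichment weights and
# per-position importance weights, transcribed from the published enrichment
# model behind the IEDB "Class I Immunogenicity" predictor (Calis et al.,
# PLoS Comput Biol 9:e1003266, 2013).  Enrichment compares amino acid
# frequencies in immunogenic vs non-immunogenic MHC-I ligands; importance
# reflects how strongly each position of a presented 9-mer contributes
# (P4-P6 dominate; anchor positions 1, 2 and the C-terminus are masked by
# default and carry weight 0).
# key	value
residue	A	0.127
residue	C	-0.175
residue	D	0.072
residue	E	0.325
residue	F	0.380
residue	G	0.110
residue	H	0.105
residue	I	0.432
residue	K	-0.700
residue	L	-0.036
residue	M	-0.570
residue	N	-0.021
residue	P	-0.036
residue	Q	-0.376
residue	R	0.168
residue	S	-0.537
residue	T	0.126
residue	V	0.134
residue	W	0.719
residue	Y	-0.012
position	1	0.00
position	2	0.00
position	3	0.10
position	4	0.31
position	5	0.30
position	6	0.29
position	7	0.26
position	8	0.18
position	9	0.00
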