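# Key functional residue sets of the E. coli CRP DNA-binding (HTH) domain.
# Positions are 1-based on the mature E. coli CRP chain (initiator Met removed).
# AR1 is tabulated with 11 residues (Pro154..Gln164) although often described
# in prose as a ten-residue patch; kept as tabulated.
category	reference_id	position	residue
AR1	EcoCRP	154	P
AR1	EcoCRP	155	D
AR1	EcoCRP	156	A
AR1	EcoCRP	157	M
AR1	EcoCRP	158	T
AR1	EcoCRP	159	H
AR1	EcoCRP	160	P
AR1	EcoCRP	161	D
AR1	EcoCRP	162	G
AR1	EcoCRP	163	M
AR1	EcoCRP	164	Q
phosphate_backbone	EcoCRP	166	K
phosphate_backbone	EcoCRP	169	R
phosphate_backbone	EcoCRP	170	Q
phosphate_backbone	EcoCRP	179	S
phosphate_backbone	EcoCRP	182	T
phosphate_backbone	EcoCRP	188	K
phosphate_backbone	EcoCRP	199	H
specific_base	EcoCRP	180	R
specific_base	EcoCRP	181	E
specific_base	EcoCRP	185	R
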