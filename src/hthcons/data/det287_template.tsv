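# Template for the RNA-polymerase alpha-CTD "287 determinant" residue set.
# The residue identities are defined in the experimental literature and are
# deliberately NOT shipped here: fill in one row per residue, 1-based on the
# ungapped reference alpha-CTD sequence named in reference_id.
category	reference_id	position	residue
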