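# Residue classes used for ProtParam-style secondary-structure fractions.
class	residues
helix	VIYFWL
turn	NGPS
sheet	EMAL
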