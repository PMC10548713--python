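# pKa set of Bjellqvist et al. (1993) Electrophoresis 14:1023-1031,
# as used by the Expasy ProtParam/Compute pI tool. 'group' is one of
# pos, neg, nterm, cterm; 'residue' is '*' for the terminal defaults.
group	residue	pka
nterm	*	7.5
pos	K	10.0
pos	R	12.0
pos	H	5.98
cterm	*	3.55
neg	D	4.05
neg	E	4.45
neg	C	9.0
neg	Y	10.0
nterm	A	7.59
nterm	M	7.0
nterm	S	6.93
nterm	P	8.36
nterm	T	6.82
nterm	V	7.44
nterm	E	7.7
cterm	D	4.55
cterm	E	4.75
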