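# Average molecular weights of the free amino acids (Da), standard
# IUPAC/Expasy values; residue mass in a chain = weight - water (18.0153)
residue	weight
A	89.0932
C	121.1582
D	133.1027
E	147.1293
F	165.1891
G	75.0666
H	155.1546
I	131.1729
K	146.1876
L	131.1729
M	149.2113
N	132.1179
P	115.1305
Q	146.1445
R	174.201
S	105.0926
T	119.1192
V	117.1463
W	204.2252
Y	181.1885
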