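from_residue	to_residue
G	L
A	L
V	L
L	V
I	V
F	L
M	L
P	L
W	L
S	T
T	S
C	S
Y	S
H	S
K	R
R	K
Q	N
N	Q
E	D
D	E
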