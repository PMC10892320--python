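# Six amino-acid property groups by volume/polarity clustering (Miyata et al. 1979).
# Editable: reports always echo the table in use.
aa	group
C	1
A	2
G	2
P	2
S	2
T	2
N	3
D	3
Q	3
E	3
H	4
K	4
R	4
I	5
L	5
M	5
V	5
F	6
W	6
Y	6
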