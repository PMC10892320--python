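# WAG equilibrium amino-acid frequencies (Whelan & Goldman 2001), sum to 1.
aa	freq
A	0.08662790866
R	0.0439720044
N	0.03908940391
D	0.0570451057
C	0.01930780193
Q	0.03672810367
E	0.05805890581
G	0.08325180833
H	0.02443130244
I	0.04846600485
L	0.08620900862
K	0.0620286062
M	0.01950270195
F	0.03843190384
P	0.04576310458
S	0.06951790695
T	0.0610127061
W	0.01438590144
Y	0.03527420353
V	0.07089560709
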