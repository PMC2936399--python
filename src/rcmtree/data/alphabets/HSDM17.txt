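# HSDM17 — homologous-structure-derived matrix reduction (Prlic et al. 2000),
# as tabulated by Peterson et al. (2009), Bioinformatics 25:1356.
A
D
KE
R
N
T
S
Q
Y
F
LIV
M
C
W
H
G
P
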