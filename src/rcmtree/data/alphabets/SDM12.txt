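# SDM12 — structure-derived matrix reduction (Prlic, Domingues & Sippl 2000),
# as tabulated by Peterson et al. (2009), Bioinformatics 25:1356.
A
D
KER
N
TSQ
YF
LIVM
C
W
H
G
P
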