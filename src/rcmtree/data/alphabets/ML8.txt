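# ML8 — Murphy, Wallqvist & Levy (2000), Protein Eng 13:149
LVIMC
AG
ST
P
FYW
EDNQ
KR
H
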