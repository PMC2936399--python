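# ML4 — Murphy, Wallqvist & Levy (2000), Protein Eng 13:149, BLOSUM50-based
# 4-group reduction: hydrophobic / small+polar / aromatic / charged+polar.
LVIMC
AGSTP
FYW
EDNQKRH
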