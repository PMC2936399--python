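# GBMR4 — generalized-bond-matrix representation reduction (Rackovsky line),
# as tabulated by Peterson et al. (2009), Bioinformatics 25:1356:
# polar/charged, hydrophobic/aromatic, glycine, proline.
ADKERNTSQ
YFLIVMCWH
G
P
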