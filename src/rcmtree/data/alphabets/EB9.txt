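# EB9 — BLOSUM62-based compressed alphabet series (Edgar 2004, NAR 32:380).
# Reconstructed by progressive BLOSUM62 merging consistent with EB5; edit to
# substitute an authoritative transcription if one is available.
AST
C
DENQ
FWY
G
H
ILMV
KR
P
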