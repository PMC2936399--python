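# EB5 — BLOSUM62-based compressed alphabet series (Edgar 2004, NAR 32:380).
# Size-5 member: the widely used {AGPST, CILMV, DENQ, FWY, HKR} grouping.
AGPST
CILMV
DENQ
FWY
HKR
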