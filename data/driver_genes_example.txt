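# Example driver-gene list for find_recurrent_variants / the --driver-genes
# option (one symbol per line).  These are genes recurrently mutated in
# mature T-cell lymphomas (TCR, NF-kB and JAK-STAT signalling, chromatin and
# DNA-damage pathways).  It is an illustrative synthetic default, not a
# published curated set; supply your own list for real analyses.
CARD11
CCR4
CD28
CREBBP
DNMT3A
FAS
FYN
IDH2
IRF4
JAK1
JAK2
JAK3
KMT2C
KMT2D
NFKB2
PIK3CD
PLCG1
PRKCB
RHOA
SETD2
SOCS1
STAT3
STAT5B
TET2
TNFAIP3
TP53
VAV1
ZEB1
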