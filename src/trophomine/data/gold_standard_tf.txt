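# Gold-standard transcription factors compiled from published expression
# studies of bovine embryo elongation, transcribed verbatim from the
# printed table (65 cells; the accompanying text counts n = 64).
# Notes, not corrected here:
#   - "ASCL2/MASH2" is one alias group (either symbol counts as the entry);
#   - SPARC is canonically a matricellular protein, not a TF, yet appears
#     in the printed table; dropping it yields the text's n = 64;
#   - the printed missed-gene list spells PHLDA1 as "PHLDA11".
ASCL2/MASH2
CDX2
c-fos
CITED1
CITED2
DLX2
DLX3
DLX4
DLX5
DNMT1
DNMT3A
DNMT3B
ELF2
EOMES
ETS1
ETS2
FOSB
FOXA2
GATA2
GATA3
GATA4
GATA5
GATA6
HAND1
HNF4A
HOXA4
HOXB9
HOXC4
HOXD10
HOXD11
HOXD13
JUN
JUND
KLF10
KLF13
KLF15
KLF3
KLF4
KLF5
KLF9
MSX1
MXI1
MYB
MYC
OSTF1
OTX2
PAX9
PHB
PHLDA1
PITX2
POU5F1
SALL1
SIX2
SIX3
SOX13
SOX15
SOX17
SOX2
SP1
SPARC
STAT2
TBX10
TBX15
TBX18
TBX5
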