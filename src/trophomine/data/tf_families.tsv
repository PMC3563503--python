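# Minimal TF-family table (symbol <TAB> family label); synthetic stand-in
# assembled from the family assignments named in the source annotations
# (homeodomain, bHLH, zinc-finger, oncogene) — not a full encyclopedia.
NANOG	homeodomain
ASCL2	bHLH
HAND1	bHLH
HES1	bHLH
ID2	bHLH
GATA3	zinc-finger
C-FOS	oncogene
CFOS	oncogene
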