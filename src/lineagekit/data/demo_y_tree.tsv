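# Demo Y-chromosome haplogroup hierarchy (child, parent). Defining SNP
# markers live in demo_y_markers.tsv (one marker per branch).
YRoot
P	YRoot
Q	P
Q1a3a1	Q
Q1a3a1a	Q1a3a1
Q1a3a1b	Q1a3a1
Q1a3a1c	Q1a3a1
R	P
R1	R
R1a	R1
R1a1	R1a
R1b1	R1
R1b1a2	R1b1
R1b1a2a1a1	R1b1a2
R1b1a2a1a1a	R1b1a2a1a1
R1b1a2a1a2	R1b1a2
R1b1a2a1a2a1b1a	R1b1a2a1a2
R1b1a2a1a2b	R1b1a2a1a2
R1b1a2a1a2c1a1a1	R1b1a2a1a2
J2	YRoot
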