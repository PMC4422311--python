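# Minimal demo mtDNA haplogroup tree (child, parent, defining variants).
# A trimmed Phylotree-style dialect covering the Native American clades
# A2/B2/C1, the B2t branch, and the African L3b outgroup.
Root
A2	Root	C64T C146T A153G A235G C16111T C16290T G16319A T16362C
A2+T16092C	A2	T16092C
A2+@T16362C	A2	@T16362C
A2w	A2	T1101C A7124G
A2w1	A2w	573.XC C16187T
B2	Root
B2t	B2	A10792G A15244G C16259T T16357C C16467T
B2t1	B2t	G15884A
C1	Root	T16298C C16327T
L3b	Root	G10086A T16124C C16278T
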