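name	ancestral	derived	branch
M242	C	T	Q
M3	C	T	Q1a3a1
M19	T	A	Q1a3a1a
M194	G	A	Q1a3a1b
M199	A	C	Q1a3a1c
M173	A	C	R1
M420	A	T	R1a
M17	G	A	R1a1
P25	C	A	R1b1
M269	C	T	R1b1a2
U106	C	T	R1b1a2a1a1
U198	G	A	R1b1a2a1a1a
M222	G	A	R1b1a2a1a2a1b1a
U152	C	T	R1b1a2a1a2b
M167	C	T	R1b1a2a1a2c1a1a1
M172	T	G	J2
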