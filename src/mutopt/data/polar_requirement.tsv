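# H WOEC730101
# D Polar requirement (Woese, 1973)
A	R	N	D	C	Q	E	G	H	I	L	K	M	F	P	S	T	W	Y	V
7	9.1	10	13	5.5	8.6	12.5	7.9	8.4	4.9	4.9	10.1	5.3	5	6.6	7.5	6.6	5.3	5.7	5.6
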