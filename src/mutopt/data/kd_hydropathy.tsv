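# H KYTJ820101
# D Hydropathy index (Kyte-Doolittle, 1982)
A	R	N	D	C	Q	E	G	H	I	L	K	M	F	P	S	T	W	Y	V
1.8	-4.5	-3.5	-3.5	2.5	-3.5	-3.5	-0.4	-3.2	4.5	3.8	-3.9	1.9	2.8	-1.6	-0.8	-0.7	-0.9	-1.3	4.2
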