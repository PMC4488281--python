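# H SYNTH-EMPAR
# D SYNTHETIC stand-in empirical replacement cost
# C d(a,b) = s(aa)+s(bb)-2*s(ab) from the BLOSUM62 similarity matrix
	A	R	N	D	C	Q	E	G	H	I	L	K	M	F	P	S	T	W	Y	V
A	0.0000	11.0000	14.0000	14.0000	13.0000	11.0000	11.0000	10.0000	16.0000	10.0000	10.0000	11.0000	11.0000	14.0000	13.0000	6.0000	9.0000	21.0000	15.0000	8.0000
R	11.0000	0.0000	11.0000	15.0000	20.0000	8.0000	10.0000	15.0000	13.0000	15.0000	13.0000	6.0000	12.0000	17.0000	16.0000	11.0000	12.0000	22.0000	16.0000	15.0000
N	14.0000	11.0000	0.0000	10.0000	21.0000	11.0000	11.0000	12.0000	12.0000	16.0000	16.0000	11.0000	15.0000	18.0000	17.0000	8.0000	11.0000	25.0000	17.0000	16.0000
D	14.0000	15.0000	10.0000	0.0000	21.0000	11.0000	7.0000	14.0000	16.0000	16.0000	18.0000	13.0000	17.0000	18.0000	15.0000	10.0000	13.0000	25.0000	19.0000	16.0000
C	13.0000	20.0000	21.0000	21.0000	0.0000	20.0000	22.0000	21.0000	23.0000	15.0000	15.0000	20.0000	16.0000	19.0000	22.0000	15.0000	16.0000	24.0000	20.0000	15.0000
Q	11.0000	8.0000	11.0000	11.0000	20.0000	0.0000	6.0000	15.0000	13.0000	15.0000	13.0000	8.0000	10.0000	17.0000	14.0000	9.0000	12.0000	20.0000	14.0000	13.0000
E	11.0000	10.0000	11.0000	7.0000	22.0000	6.0000	0.0000	15.0000	13.0000	15.0000	15.0000	8.0000	14.0000	17.0000	14.0000	9.0000	12.0000	22.0000	16.0000	13.0000
G	10.0000	15.0000	12.0000	14.0000	21.0000	15.0000	15.0000	0.0000	18.0000	18.0000	18.0000	15.0000	17.0000	18.0000	17.0000	10.0000	15.0000	21.0000	19.0000	16.0000
H	16.0000	13.0000	12.0000	16.0000	23.0000	13.0000	13.0000	18.0000	0.0000	18.0000	18.0000	15.0000	17.0000	16.0000	19.0000	14.0000	17.0000	23.0000	11.0000	18.0000
I	10.0000	15.0000	16.0000	16.0000	15.0000	15.0000	15.0000	18.0000	18.0000	0.0000	4.0000	15.0000	7.0000	10.0000	17.0000	12.0000	11.0000	21.0000	13.0000	2.0000
L	10.0000	13.0000	16.0000	18.0000	15.0000	13.0000	15.0000	18.0000	18.0000	4.0000	0.0000	13.0000	5.0000	10.0000	17.0000	12.0000	11.0000	19.0000	13.0000	6.0000
K	11.0000	6.0000	11.0000	13.0000	20.0000	8.0000	8.0000	15.0000	15.0000	15.0000	13.0000	0.0000	12.0000	17.0000	14.0000	9.0000	12.0000	22.0000	16.0000	13.0000
M	11.0000	12.0000	15.0000	17.0000	16.0000	10.0000	14.0000	17.0000	17.0000	7.0000	5.0000	12.0000	0.0000	11.0000	16.0000	11.0000	12.0000	18.0000	14.0000	7.0000
F	14.0000	17.0000	18.0000	18.0000	19.0000	17.0000	17.0000	18.0000	16.0000	10.0000	10.0000	17.0000	11.0000	0.0000	21.0000	14.0000	15.0000	15.0000	7.0000	12.0000
P	13.0000	16.0000	17.0000	15.0000	22.0000	14.0000	14.0000	17.0000	19.0000	17.0000	17.0000	14.0000	16.0000	21.0000	0.0000	13.0000	14.0000	26.0000	20.0000	15.0000
S	6.0000	11.0000	8.0000	10.0000	15.0000	9.0000	9.0000	10.0000	14.0000	12.0000	12.0000	9.0000	11.0000	14.0000	13.0000	0.0000	7.0000	21.0000	15.0000	12.0000
T	9.0000	12.0000	11.0000	13.0000	16.0000	12.0000	12.0000	15.0000	17.0000	11.0000	11.0000	12.0000	12.0000	15.0000	14.0000	7.0000	0.0000	20.0000	16.0000	9.0000
W	21.0000	22.0000	25.0000	25.0000	24.0000	20.0000	22.0000	21.0000	23.0000	21.0000	19.0000	22.0000	18.0000	15.0000	26.0000	21.0000	20.0000	0.0000	14.0000	21.0000
Y	15.0000	16.0000	17.0000	19.0000	20.0000	14.0000	16.0000	19.0000	11.0000	13.0000	13.0000	16.0000	14.0000	7.0000	20.0000	15.0000	16.0000	14.0000	0.0000	13.0000
V	8.0000	15.0000	16.0000	16.0000	15.0000	13.0000	13.0000	16.0000	18.0000	2.0000	6.0000	13.0000	7.0000	12.0000	15.0000	12.0000	9.0000	21.0000	13.0000	0.0000
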