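# H GRAR740104
# D Chemical distance (Grantham, 1974), computed
# C from composition/polarity/volume with alpha=1.833 beta=0.1018 gamma=0.000399
	A	R	N	D	C	Q	E	G	H	I	L	K	M	F	P	S	T	W	Y	V
A	0.0000	111.4113	110.5636	125.9144	195.2609	90.8809	106.8533	60.0745	85.6065	93.7859	96.3139	105.7101	84.5509	112.7299	26.9098	99.2632	58.0998	147.9214	111.7354	64.5152
R	111.4113	0.0000	85.2262	95.9399	179.7716	42.8704	54.0901	125.2942	28.8572	97.7152	102.0146	26.0382	91.7591	97.1607	102.8503	109.3572	71.0646	101.4240	77.2093	95.9234
N	110.5636	85.2262	0.0000	23.0357	138.9494	45.8125	40.9128	79.4505	68.4450	149.1105	152.5318	94.0065	141.3388	158.3207	90.2763	46.3007	64.8597	174.0109	142.4169	133.0529
D	125.9144	95.9399	23.0357	0.0000	153.7769	61.3653	44.6635	93.8912	81.3451	168.3026	171.9837	101.5907	160.2377	176.7590	108.0520	65.5571	85.1883	190.8036	160.1483	152.2138
C	195.2609	179.7716	138.9494	153.7769	0.0000	154.4342	169.6609	158.4404	174.0719	197.5099	197.6893	201.8451	195.8122	204.6580	168.8129	111.8198	149.1258	214.6450	193.9802	191.4847
Q	90.8809	42.8704	45.8125	61.3653	154.4342	0.0000	29.3123	87.2813	24.1157	108.7094	112.5897	53.2985	101.0322	115.7394	75.2350	68.2878	41.1590	130.3761	98.9135	96.4527
E	106.8533	54.0901	40.9128	44.6635	169.6609	29.3123	0.0000	97.9809	40.8479	134.3391	138.5255	56.9429	126.2512	140.3970	93.8545	79.8928	65.5877	152.4602	122.9388	121.4885
G	60.0745	125.2942	79.4505	93.8912	158.4404	87.2813	97.9809	0.0000	97.6620	135.5974	137.8732	126.6247	127.1123	153.3274	41.6840	55.3402	59.2345	184.0326	147.1200	108.9308
H	85.6065	28.8572	68.4450	81.3451	174.0719	24.1157	40.8479	97.6620	0.0000	94.4619	98.8232	32.4456	86.4578	100.1269	76.3777	89.0528	46.8145	114.7122	83.4383	84.0036
I	93.7859	97.7152	149.1105	168.3026	197.5099	108.7094	134.3391	135.5974	94.4619	0.0000	4.8615	101.7463	10.1343	21.3051	95.5019	141.9849	89.4006	60.6077	33.0913	29.6481
L	96.3139	102.0146	152.5318	171.9837	197.6893	112.5897	138.5255	137.8732	98.8232	4.8615	0.0000	106.4757	14.3220	21.8527	97.9051	144.2692	92.4761	61.0609	35.7244	31.8267
K	105.7101	26.0382	94.0065	101.5907	201.8451	53.2985	56.9429	126.6247	32.4456	101.7463	106.4757	0.0000	94.6147	102.2760	102.8494	120.6915	77.8436	109.5788	84.8982	97.1253
M	84.5509	91.7591	141.3388	160.2377	195.8122	101.0322	126.2512	127.1123	86.4578	10.1343	14.3220	94.6147	0.0000	28.5655	86.7090	135.0417	81.1466	66.7247	35.2691	21.5502
F	112.7299	97.1607	158.3207	176.7590	204.6580	115.7394	140.3970	153.3274	100.1269	21.3051	21.8527	102.2760	28.5655	0.0000	113.8771	155.0120	102.9944	39.7074	21.6382	50.0010
P	26.9098	102.8503	90.2763	108.0520	168.8129	75.2350	93.8545	41.6840	76.3777	95.5019	97.9051	102.8494	86.7090	113.8771	0.0000	73.4493	37.6132	146.8142	109.7601	67.8760
S	99.2632	109.3572	46.3007	65.5571	111.8198	68.2878	79.8928	55.3402	89.0528	141.9849	144.2692	120.6915	135.0417	155.0120	73.4493	0.0000	57.8252	176.8104	143.2961	123.1962
T	58.0998	71.0646	64.8597	85.1883	149.1258	41.1590	65.5877	59.2345	46.8145	89.4006	92.4761	77.8436	81.1466	102.9944	37.6132	57.8252	0.0000	128.4851	92.3693	69.5879
W	147.9214	101.4240	174.0109	190.8036	214.6450	130.3761	152.4602	184.0326	114.7122	60.6077	61.0609	109.5788	66.7247	39.7074	146.8142	176.8104	128.4851	0.0000	37.1627	88.0796
Y	111.7354	77.2093	142.4169	160.1483	193.9802	98.9135	122.9388	147.1200	83.4383	33.0913	35.7244	84.8982	35.2691	21.6382	109.7601	143.2961	92.3693	37.1627	0.0000	54.7349
V	64.5152	95.9234	133.0529	152.2138	191.4847	96.4527	121.4885	108.9308	84.0036	29.6481	31.8267	97.1253	21.5502	50.0010	67.8760	123.1962	69.5879	88.0796	54.7349	0.0000
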