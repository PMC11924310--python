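cluster_id	position	arctic_aa	temperate_aa	functional_annotation	functional_group
9895	384	N	D, F, K, T	Methylation of tRNAs	[J] Translation, ribosomal structure and biogenesis
1375	52	S	A, D, P, V	Zinc finger, C3HC4 type	[K] Transcription
2720	413	N	Q, S	Zinc finger, Nab2-type	[K] Transcription
6123	30	A, I	V	Sec23/Sec24 zinc finger	[K] Transcription
2998	749	E	C, G, I, Q, R, S, T	DNA mismatch repair protein Mlh1	[L] Replication, recombination and repair
7630	448	E	K, Q, S	DNA polymerase alpha/epsilon subunit B	[L] Replication, recombination and repair
7700	423	V	E, G, S, T	Sugar transporter	[G] Carbohydrate transport and metabolism
5037	269	Q	E, K, R	Membrane-bound acyltransferase	[I] Lipid transport and metabolism
5781	218	K	E, G, S, V	Oxidation-reduction (dehydrogense)	[I] Lipid transport and metabolism and [Q] Secondary metabolites biosynthesis, transport and catabolism
6653	168	E	D, G, Q	All-trans-retinol 13,14-reductase	[I] Lipid transport and metabolism and [Q] Secondary metabolites biosynthesis, transport and catabolism
8045	893	S	A, V	ABC transporter	[Q] Secondary metabolites biosynthesis, transport and catabolism
8045	1162	V	A, I
8045	1259	A	I, K, V
631	616	W	A, F, H, L, Y	Chitinase class I	[R] General function prediction only
557	16	L	A, F, I, S, T	—	[S] Function unknown
908	158	D, F, T	S	—	[S] Function unknown
2702	371	C	F, S, Y	—	[S] Function unknown
2993	141	S	A, E, H, K, Q, R	—	[S] Function unknown
3485	150	S	A, D, E, T	—	[S] Function unknown
4072	662	M	A, G, L, P, S, T, V	—	[S] Function unknown
4756	49	A	E, N, T, V	—	[S] Function unknown
4990	33	E	A, D, K, N, Q, S, T, V	—	[S] Function unknown
6457	27	A	K, P, S	—	[S] Function unknown
10130	156	N	D, F, G, L, S	—	[S] Function unknown
11282	276	N	K, L, R, V	—	[S] Function unknown
11341	215	M	I, K, L, S	—	[S] Function unknown
12554	333	L	V	—	[S] Function unknown
13375	292	A, F, I	V	—	[S] Function unknown
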