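index	region	allowed_residues	conserved	label	canonical
1	basic	*	0		N
2	basic	*	0		R
3	basic	*	0		E
4	basic	*	0		R
5	basic	*	0		R
6	basic	*	0		S
7	basic	*	0		R
8	basic	*	0		K
9	basic	HK	1	His/Lys-9	H
10	basic	*	0		A
11	basic	*	0		E
12	basic	*	0		N
13	basic	E	1	Glu-13	E
14	basic	RK	1	Arg-14	R
15	basic	*	0	Gln-15	Q
16	basic	R	1	Arg-16	R
17	basic	RK	1	Arg-17	R
18	helix1	*	0		D
19	helix1	*	0		E
20	helix1	ILV	1	Ile-20	I
21	helix1	N	1	Asn-21	N
22	helix1	*	0	Gln-22	Q
23	helix1	*	0		V
24	helix1	LIVM	1	Leu-24	L
25	helix1	*	0		R
26	helix1	*	0		E
27	helix1	L	1	Leu-27	L
28	helix1	QKR	1	Gln-28	Q
29	helix1	*	0		V
30	helix1	*	0		K
31	helix1	*	0	Val-31	V
32	helix1	*	0		M
33	loop	*	0		G
34	loop	*	0		G
35	loop	*	0		A
36	loop	KR	1	Lys-36	K
37	loop	*	0		A
38	helix2	DE	1	Asp-38	D
39	helix2	*	0		T
40	helix2	*	0		L
41	helix2	*	0		Q
42	helix2	KR	1	Lys-42	K
43	helix2	ILV	1	Ile-43	I
44	helix2	*	0		N
45	helix2	*	0		E
46	helix2	LM	1	Leu-46	L
47	helix2	*	0		R
48	helix2	*	0		S
49	helix2	*	0		E
50	helix2	AST	1	Ala-50	A
51	helix2	VIL	1	Val-51	V
52	helix2	*	0		Q
53	helix2	*	0		S
54	helix2	L	1	Leu-54	L
55	helix2	*	0		M
56	helix2	*	0		E
57	helix2	RK	1	Arg-57	R
58	helix2	*	0		A
59	helix2	*	0		L
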