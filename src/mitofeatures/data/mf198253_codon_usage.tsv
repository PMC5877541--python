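amino_acid	codon	n	rscu	n_j	rscu_j	n_n	rscu_n
F	UUU	208	1.36	85	0.98	123	1.86
F	UUC	98	0.64	89	1.02	9	0.14
L	UUA	280	2.6	131	2.13	149	3.23
L	UUG	108	1	12	0.2	96	2.08
L	CUU	67	0.62	53	0.86	14	0.3
L	CUC	67	0.62	66	1.07	1	0.02
L	CUA	112	1.04	97	1.58	15	0.32
L	CUG	12	0.11	10	0.16	2	0.04
I	AUU	213	1.46	133	1.29	80	1.86
I	AUC	79	0.54	73	0.71	6	0.14
M	AUA	141	1.45	100	1.72	41	1.04
M	AUG	54	0.55	16	0.28	38	0.96
V	GUU	82	1.38	29	0.88	53	2.02
V	GUC	44	0.74	37	1.12	7	0.27
V	GUA	70	1.18	55	1.67	15	0.57
V	GUG	41	0.69	11	0.33	30	1.14
S	UCU	94	2.32	39	1.72	55	3.08
S	UCC	30	0.74	29	1.28	1	0.06
S	UCA	63	1.56	48	2.12	15	0.84
S	UCG	15	0.37	7	0.31	8	0.45
P	CCU	59	1.55	34	1.21	25	2.5
P	CCC	48	1.26	45	1.61	3	0.3
P	CCA	36	0.95	29	1.04	7	0.7
P	CCG	9	0.24	4	0.14	5	0.5
T	ACU	66	1.25	43	1.07	23	1.8
T	ACC	59	1.11	58	1.44	1	0.08
T	ACA	73	1.38	56	1.39	17	1.33
T	ACG	14	0.26	4	0.1	10	0.78
A	GCU	84	1.51	48	1.29	36	1.97
A	GCC	76	1.37	72	1.93	4	0.22
A	GCA	37	0.67	27	0.72	10	0.55
A	GCG	25	0.45	2	0.05	23	1.26
Y	UAU	106	1.39	32	0.84	74	1.95
Y	UAC	46	0.61	44	1.16	2	0.05
*	UAA	9	1.64	7	1.75	2	1.33
*	UAG	2	0.36	1	0.25	1	0.67
H	CAU	46	1.12	30	0.91	16	2
H	CAC	36	0.88	36	1.09	0	0
Q	CAA	70	1.71	57	1.97	13	1.08
Q	CAG	12	0.29	1	0.03	11	0.92
N	AAU	110	1.44	63	1.19	47	2
N	AAC	43	0.56	43	0.81	0	0
K	AAA	35	1.03	29	1.66	6	0.36
K	AAG	33	0.97	6	0.34	27	1.64
D	GAU	51	1.4	31	1.19	20	1.9
D	GAC	22	0.6	21	0.81	1	0.1
E	GAA	55	1.34	43	1.87	12	0.67
E	GAG	27	0.66	3	0.13	24	1.33
C	UGU	38	1.69	7	1	31	2
C	UGC	7	0.31	7	1	0	0
W	UGA	82	1.56	63	1.85	19	1.03
W	UGG	23	0.44	5	0.15	18	0.97
R	CGU	13	0.81	4	0.41	9	1.44
R	CGC	2	0.13	2	0.21	0	0
R	CGA	33	2.06	29	2.97	4	0.64
R	CGG	16	1	4	0.41	12	1.92
S	AGU	49	1.21	22	0.97	27	1.51
S	AGC	18	0.44	12	0.53	6	0.34
S	AGA	52	1.28	24	1.06	28	1.57
S	AGG	3	0.07	0	0	3	0.17
G	GGU	56	0.91	21	0.6	35	1.32
G	GGC	22	0.36	14	0.4	8	0.3
G	GGA	92	1.5	79	2.27	13	0.49
G	GGG	75	1.22	25	0.72	50	1.89
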