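partition	pct_t	pct_c	pct_a	pct_g	pct_at	at_skew	gc_skew	n_nucleotides
Whole genome	30.2	21.7	36.5	11.6	66.7	0.09	-0.303	16146
PCGs	37.6	18.9	26.5	17.0	64.1	-0.17	-0.052	11244
PCGs codon1	40.6	20.7	21.9	16.9	62.4	-0.30	-0.102	3743
PCGs codon2	37.5	18.1	28.5	15.9	66.0	-0.14	-0.063	3743
PCGs codon3	34.8	17.8	29.1	18.2	64.0	-0.09	0.011	3743
PCG-J	32.9	24.5	28.9	13.7	61.8	-0.07	-0.281	6921
PCG-J codon1	36.4	23.1	24.5	16.0	60.9	-0.20	-0.182	2307
PCG-J codon2	32.0	27.2	30.4	10.3	62.4	-0.03	-0.450	2307
PCG-J codon3	30.4	23.0	31.8	14.8	62.1	0.02	-0.217	2307
PCG-N	45.1	9.9	22.7	22.2	67.8	-0.33	0.383	4323
PCG-N codon1	41.9	9.5	25.0	23.6	66.9	-0.25	0.427	1441
PCG-N codon2	47.1	16.9	17.8	18.3	64.9	-0.45	0.040	1441
PCG-N codon3	46.4	3.4	25.4	24.8	71.8	-0.29	0.759	1441
tRNAs	34.6	13.9	34.6	16.9	69.2	0.00	0.100	1487
tRNA-J	33.8	15.1	36.2	14.9	70.0	0.03	-0.007	946
tRNA-N	36.0	11.6	31.8	20.5	67.8	-0.06	0.276	541
rRNAs	39.9	9.4	31.6	19.1	71.5	-0.12	0.338	2129
lrRNA	40.3	8.3	32.9	18.5	73.2	-0.10	0.382	1329
srRNA	39.1	11.4	29.5	20.0	68.6	-0.14	0.275	800
CR	35.5	13.3	43.6	7.6	79.1	0.10	-0.272	1249
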