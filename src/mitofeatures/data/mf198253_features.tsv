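gene	direction	start	end	anticodon	anticodon_start	anticodon_end	start_codon	stop_codon	intergenic
tRNA-Ile	F	1	67	GAT	30	32
tRNA-Gln	R	65	133	TTG	101	103			-3
tRNA-Met	F	135	203	CAT	165	167			1
ND2	F	204	1,238				ATG	TAA	0
tRNA-Trp	F	1,237	1,305	TCA	1,267	1,269			-2
tRNA-Cys	R	1,298	1,364	GCA	1,331	1,333			-8
tRNA-Tyr	R	1,367	1,433	GTA	1,398	1,400			2
COI	F	1,426	2,982				ATT	TAA	-8
tRNA-Leu(UUR)	F	3,002	3,067	TAA	3,031	3,033			19
COII	F	3,081	3,768				ATG	T-	13
tRNA-Lys	F	3,769	3,839	CTT	3,799	3,801			0
tRNA-Asp	F	3,839	3,907	GTC	3,869	3,871			-1
ATP8	F	3,908	4,066				ATG	TAA	0
ATP6	F	4,060	4,737				ATG	TAA	-7
COIII	F	4,737	5,525				ATG	TAA	-1
tRNA-Gly	F	5,528	5,593	TCC	5,558	5,560			2
ND3	F	5,594	5,947				ATC	TAG	0
tRNA-Ala	F	5,946	6,011	TGC	5,975	5,977			-2
tRNA-Arg	F	6,013	6,077	TCG	6,042	6,044			1
tRNA-Asn	F	6,082	6,147	GTT	6,112	6,114			4
tRNA-Ser(AGN)	F	6,148	6,214	GCT	6,173	6,175			0
tRNA-Glu	F	6,215	6,281	TTC	6,246	6,248			0
tRNA-Phe	R	6,287	6,351	GAA	6,320	6,322			5
ND5	R	6,352	8,086				GTG	T-	0
tRNA-His	R	8,087	8,154	GTG	8,121	8,123			0
ND4	R	8,159	9,499				ATG	TAA	4
ND4L	R	9,493	9,789				ATG	TAA	-7
tRNA-Thr	F	9,792	9,859	TGT	9,822	9,824			2
tRNA-Pro	R	9,861	9,928	TGG	9,896	9,898			1
ND6	F	9,930	10,454				ATC	TAA	1
CytB	F	10,454	11,590				ATG	TAA	-1
tRNA-Ser(UCN)	F	11,590	11,659	TGA	11,621	11,623			-1
ND1	R	11,680	12,630				TTG	TAG	20
tRNA-Leu(CUN)	R	12,632	12,697	TAG	12,666	12,668			1
lrRNA	R	12,698	14,026						0
tRNA-Val	R	14,027	14,097	TAC	14,062	14,064			0
srRNA	R	14,098	14,897						0
CR		14,898	16,146						0
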