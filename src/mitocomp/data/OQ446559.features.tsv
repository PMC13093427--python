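gene	type	start	end	strand	anticodon	start_codon	stop_codon
trnF	tRNA	1	69	H	TTC	.	.
12S	rRNA	70	1042	H	.	.	.
trnV	tRNA	1043	1113	H	GTA	.	.
16S	rRNA	1114	2813	H	.	.	.
trnL2	tRNA	2815	2889	H	TTA	.	.
ND1	PCG	2899	3867	H	.	ATG	TAA
trnI	tRNA	3870	3940	H	ATC	.	.
trnQ	tRNA	3940	4010	L	CAA	.	.
trnM	tRNA	4010	4078	H	ATG	.	.
ND2	PCG	4079	5123	H	.	ATG	T--
trnW	tRNA	5124	5192	H	TGA	.	.
trnA	tRNA	5194	5262	L	GCA	.	.
trnN	tRNA	5264	5336	L	AAC	.	.
trnC	tRNA	5371	5436	L	TGC	.	.
trnY	tRNA	5437	5506	L	TAC	.	.
COI	PCG	5508	7056	H	.	GTG	T--
trnS2	tRNA	7057	7128	L	TCA	.	.
trnD	tRNA	7133	7204	H	GAC	.	.
COII	PCG	7210	7900	H	.	ATG	T--
trnK	tRNA	7901	7974	H	AAA	.	.
ATP8	PCG	7976	8143	H	.	ATG	TAA
ATP6	PCG	8134	8817	H	.	ATG	TAA
COIII	PCG	8817	9601	H	.	ATG	TA-
trnG	tRNA	9602	9672	H	GGA	.	.
ND3	PCG	9673	10021	H	.	ATG	T--
trnR	tRNA	10022	10091	H	CGA	.	.
ND4L	PCG	10092	10388	H	.	ATG	TAA
ND4	PCG	10382	11762	H	.	ATG	T--
trnH	tRNA	11763	11832	H	CAC	.	.
trnS1	tRNA	11833	11899	H	AGC	.	.
trnL1	tRNA	11900	11972	H	CTA	.	.
ND5	PCG	11973	13811	H	.	ATG	TAA
ND6	PCG	13807	14328	L	.	ATG	AGA
trnE	tRNA	14329	14396	L	GAA	.	.
Cytb	PCG	14402	15542	H	.	ATG	T--
trnT	tRNA	15543	15615	H	ACA	.	.
trnP	tRNA	15618	15687	L	CCA	.	.
CR	CR	15688	16176	H	.	.	.
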