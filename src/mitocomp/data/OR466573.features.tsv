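gene	type	start	end	strand	anticodon	start_codon	stop_codon
trnF	tRNA	1	69	H	TTC	.	.
12S	rRNA	70	1041	H	.	.	.
trnV	tRNA	1042	1112	H	GTA	.	.
16S	rRNA	1113	2813	H	.	.	.
trnL2	tRNA	2814	2888	H	TTA	.	.
ND1	PCG	2898	3866	H	.	ATG	TAA
trnI	tRNA	3869	3939	H	ATC	.	.
trnQ	tRNA	3939	4009	L	CAA	.	.
trnM	tRNA	4009	4077	H	ATG	.	.
ND2	PCG	4078	5122	H	.	ATG	T--
trnW	tRNA	5123	5191	H	TGA	.	.
trnA	tRNA	5193	5261	L	GCA	.	.
trnN	tRNA	5263	5335	L	AAC	.	.
trnC	tRNA	5370	5435	L	TGC	.	.
trnY	tRNA	5435	5505	L	TAC	.	.
COI	PCG	5507	7063	H	.	GTG	AGG
trnS2	tRNA	7055	7126	L	TCA	.	.
trnD	tRNA	7131	7202	H	GAC	.	.
COII	PCG	7208	7898	H	.	ATG	T--
trnK	tRNA	7899	7972	H	AAA	.	.
ATP8	PCG	7974	8141	H	.	ATG	TAA
ATP6	PCG	8132	8814	H	.	ATG	TA-
COIII	PCG	8815	9599	H	.	ATG	TA-
trnG	tRNA	9600	9670	H	GGA	.	.
ND3	PCG	9671	10019	H	.	ATG	T--
trnR	tRNA	10020	10089	H	CGA	.	.
ND4L	PCG	10090	10386	H	.	ATG	TAA
ND4	PCG	10380	11760	H	.	ATG	T--
trnH	tRNA	11761	11830	H	CAC	.	.
trnS1	tRNA	11831	11897	H	AGC	.	.
trnL1	tRNA	11898	11970	H	CTA	.	.
ND5	PCG	11971	13809	H	.	ATG	TAA
ND6	PCG	13805	14326	L	.	ATG	AGA
trnE	tRNA	14327	14394	L	GAA	.	.
Cytb	PCG	14400	15540	H	.	ATG	T--
trnT	tRNA	15541	15613	H	ACA	.	.
trnP	tRNA	15617	15686	L	CCA	.	.
CR	CR	15687	16943	H	.	.	.
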