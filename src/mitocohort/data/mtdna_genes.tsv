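# Human mtDNA gene map on the revised Cambridge Reference Sequence (NC_012920.1).
# Coordinates are 1-based inclusive. The genome is circular (16,569 bp); only the
# D-loop interval wraps the origin (start > end). strand: H = heavy, L = light.
# category: protein | tRNA | rRNA | dloop. complex: OXPHOS complex for protein
# genes (I, III, IV, V), "none" otherwise.
# name	start	end	strand	category	complex
D-loop	16024	576	H	dloop	none
MT-TF	577	647	H	tRNA	none
MT-RNR1	648	1601	H	rRNA	none
MT-TV	1602	1670	H	tRNA	none
MT-RNR2	1671	3229	H	rRNA	none
MT-TL1	3230	3304	H	tRNA	none
MT-ND1	3307	4262	H	protein	I
MT-TI	4263	4331	H	tRNA	none
MT-TQ	4329	4400	L	tRNA	none
MT-TM	4402	4469	H	tRNA	none
MT-ND2	4470	5511	H	protein	I
MT-TW	5512	5579	H	tRNA	none
MT-TA	5587	5655	L	tRNA	none
MT-TN	5657	5729	L	tRNA	none
MT-TC	5761	5826	L	tRNA	none
MT-TY	5826	5891	L	tRNA	none
MT-CO1	5904	7445	H	protein	IV
MT-TS1	7446	7514	L	tRNA	none
MT-TD	7518	7585	H	tRNA	none
MT-CO2	7586	8269	H	protein	IV
MT-TK	8295	8364	H	tRNA	none
MT-ATP8	8366	8572	H	protein	V
MT-ATP6	8527	9207	H	protein	V
MT-CO3	9207	9990	H	protein	IV
MT-TG	9991	10058	H	tRNA	none
MT-ND3	10059	10404	H	protein	I
MT-TR	10405	10469	H	tRNA	none
MT-ND4L	10470	10766	H	protein	I
MT-ND4	10760	12137	H	protein	I
MT-TH	12138	12206	H	tRNA	none
MT-TS2	12207	12265	H	tRNA	none
MT-TL2	12266	12336	H	tRNA	none
MT-ND5	12337	14148	H	protein	I
MT-ND6	14149	14673	L	protein	I
MT-TE	14674	14742	L	tRNA	none
MT-CYB	14747	15887	H	protein	III
MT-TT	15888	15953	H	tRNA	none
MT-TP	15956	16023	L	tRNA	none
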