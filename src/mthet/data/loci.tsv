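name	start	end	strand	class
MT-DLOOP	16024	576	L	D-loop
MT-TF	577	647	L	tRNA
MT-RNR1	648	1601	L	rRNA
MT-TV	1602	1670	L	tRNA
MT-RNR2	1671	3229	L	rRNA
MT-TL1	3230	3304	L	tRNA
MT-ND1	3307	4262	L	protein
MT-TI	4263	4331	L	tRNA
MT-TQ	4329	4400	H	tRNA
MT-TM	4402	4469	L	tRNA
MT-ND2	4470	5511	L	protein
MT-TW	5512	5579	L	tRNA
MT-TA	5587	5655	H	tRNA
MT-TN	5657	5729	H	tRNA
MT-TC	5761	5826	H	tRNA
MT-TY	5826	5891	H	tRNA
MT-CO1	5904	7445	L	protein
MT-TS1	7446	7514	H	tRNA
MT-TD	7518	7585	L	tRNA
MT-CO2	7586	8269	L	protein
MT-TK	8295	8364	L	tRNA
MT-ATP8	8366	8572	L	protein
MT-ATP6	8527	9207	L	protein
MT-CO3	9207	9990	L	protein
MT-TG	9991	10058	L	tRNA
MT-ND3	10059	10404	L	protein
MT-TR	10405	10469	L	tRNA
MT-ND4L	10470	10766	L	protein
MT-ND4	10760	12137	L	protein
MT-TH	12138	12206	L	tRNA
MT-TS2	12207	12265	L	tRNA
MT-TL2	12266	12336	L	tRNA
MT-ND5	12337	14148	L	protein
MT-ND6	14149	14673	H	protein
MT-TE	14674	14742	H	tRNA
MT-CYB	14747	15887	L	protein
MT-TT	15888	15953	L	tRNA
MT-TP	15956	16023	H	tRNA
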