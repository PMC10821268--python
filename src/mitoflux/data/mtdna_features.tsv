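# Human mitochondrial genome (rCRS, NC_012920.1, L=16569) gene features.
# 1-based inclusive coordinates; wrap-around intervals have end < start.
# The D_loop row uses the control-region amplicon bounds 16067-644.
name	start	end	strand	class
D-loop	16067	644	+	D_loop
TRNF	577	647	+	tRNA
RNR1	648	1601	+	rRNA
TRNV	1602	1670	+	tRNA
RNR2	1671	3229	+	rRNA
TRNL1	3230	3304	+	tRNA
ND1	3307	4262	+	protein_coding
TRNI	4263	4331	+	tRNA
TRNQ	4329	4400	-	tRNA
TRNM	4402	4469	+	tRNA
ND2	4470	5511	+	protein_coding
TRNW	5512	5579	+	tRNA
TRNA	5587	5655	-	tRNA
TRNN	5657	5729	-	tRNA
TRNC	5761	5826	-	tRNA
TRNY	5826	5891	-	tRNA
COX1	5904	7445	+	protein_coding
TRNS1	7446	7514	-	tRNA
TRND	7518	7585	+	tRNA
COX2	7586	8269	+	protein_coding
TRNK	8295	8364	+	tRNA
ATP8	8366	8572	+	protein_coding
ATP6	8527	9207	+	protein_coding
COX3	9207	9990	+	protein_coding
TRNG	9991	10058	+	tRNA
ND3	10059	10404	+	protein_coding
TRNR	10405	10469	+	tRNA
ND4L	10470	10766	+	protein_coding
ND4	10760	12137	+	protein_coding
TRNH	12138	12206	+	tRNA
TRNS2	12207	12265	+	tRNA
TRNL2	12266	12336	+	tRNA
ND5	12337	14148	+	protein_coding
ND6	14149	14673	-	protein_coding
TRNE	14674	14742	-	tRNA
CYTB	14747	15887	+	protein_coding
TRNT	15888	15953	+	tRNA
TRNP	15956	16023	-	tRNA
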