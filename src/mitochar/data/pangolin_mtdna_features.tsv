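name	category	from	to	anticodon	strand
tRNA-Phe	tRNA	1	68	GAA	H
12S ribosomal RNA	rRNA	69	1028	.	H
tRNA-Val	tRNA	1028	1093	UAC	H
16S ribosomal RNA	rRNA	1094	2659	.	H
tRNA-Leu(UAA)	tRNA	2660	2733	UAA	H
ND1	PCG	2737	3693	.	H
tRNA-Ile	tRNA	3693	3761	GAU	H
tRNA-Gln	tRNA	3759	3831	UUG	L
tRNA-Met	tRNA	3833	3901	CAU	H
ND2	PCG	3875	4913	.	H
tRNA-Trp	tRNA	4941	5007	UCA	H
tRNA-Ala	tRNA	5011	5079	UGC	L
tRNA-Asn	tRNA	5081	5153	GUU	L
tRNA-Cys	tRNA	5186	5250	GCA	L
tRNA-Tyr	tRNA	5251	5317	GUA	L
COX1	PCG	5319	6869	.	H
tRNA-Ser(UGA)	tRNA	6865	6933	UGA	L
tRNA-Asp	tRNA	6941	7007	GUC	H
COX2	PCG	7008	7691	.	H
tRNA-Lys	tRNA	7694	7757	UUU	H
ATP8	PCG	7759	7959	.	H
ATP6	PCG	7920	8600	.	H
COX3	PCG	8600	9383	.	H
tRNA-Gly	tRNA	9384	9452	UCC	H
ND3	PCG	9453	9799	.	H
tRNA-Arg	tRNA	9800	9866	UCG	H
ND4L	PCG	9867	10163	.	H
ND4	PCG	10157	11534	.	H
tRNA-His	tRNA	11535	11602	GUG	H
tRNA-Ser(GCU)	tRNA	11603	11661	GCU	H
tRNA-Leu(UAG)	tRNA	11663	11733	UAG	H
ND5	PCG	11743	13554	.	H
ND6	PCG	13538	14062	.	L
tRNA-Glu	tRNA	14063	14131	UUC	L
CYTB	PCG	14135	15274	.	H
tRNA-Thr	tRNA	15275	15341	UGU	H
tRNA-Pro	tRNA	15341	15407	UGG	L
D_loop	control	15521	16570	.	H
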