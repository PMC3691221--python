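name	class	start	stop	strand	start_codon	stop_class	anticodon	size	intergenic
tRNA-Phe	tRNA	1	69	H				69	0
12S	rRNA	70	1012	H				943	0
tRNA-Val	tRNA	1013	1084	H				72	0
16S	rRNA	1085	2776	H				1692	0
tRNA-Leu	tRNA	2777	2850	H			UAA	74	0
ND1	CDS	2851	3825	H	ATG	TAG		975	3
tRNA-Ile	tRNA	3829	3898	H			GAU	70	-1
tRNA-Gln	tRNA	3898	3968	L			UUG	71	-1
tRNA-Met	tRNA	3968	4036	H			CAU	69	0
ND2	CDS	4037	5082	H	ATG	TA+		1046	0
tRNA-Trp	tRNA	5083	5154	H				72	1
tRNA-Ala	tRNA	5156	5224	L				69	1
tRNA-Asn	tRNA	5226	5298	L				73	5
OL	OL	5304	5333	L				30	0
tRNA-Cys	tRNA	5334	5399	L				66	0
tRNA-Tyr	tRNA	5400	5469	L				70	1
COX1	CDS	5471	7066	H	GTG	TAA		1596	0
tRNA-Ser	tRNA	7067	7137	L			UGA	71	3
tRNA-Asp	tRNA	7141	7213	H				73	5
COX2	CDS	7219	7909	H	ATG	T++		691	0
tRNA-Lys	tRNA	7910	7983	H				74	1
ATP8	CDS	7985	8152	H	ATG	TAA		168	-10
ATP6	CDS	8143	8825	H	ATG	TA+		683	0
COX3	CDS	8826	9609	H	ATG	T++		784	0
tRNA-Gly	tRNA	9610	9681	H				72	0
ND3	CDS	9682	10030	H	ATG	T++		349	0
tRNA-Arg	tRNA	10031	10099	H				69	0
ND4L	CDS	10100	10396	H	ATG	TAA		297	-7
ND4	CDS	10390	11770	H	ATG	T++		1381	0
tRNA-His	tRNA	11771	11839	H				69	0
tRNA-Ser2	tRNA	11840	11906	H			GCU	67	4
tRNA-Leu2	tRNA	11911	11983	H			UAG	73	0
ND5	CDS	11984	13822	H	ATG	TAA		1839	-4
ND6	CDS	13819	14340	L	ATG	TAG		522	0
tRNA-Glu	tRNA	14341	14409	L				69	4
CYTB	CDS	14414	15554	H	ATG	T++		1141	0
tRNA-Thr	tRNA	15555	15626	H				72	0
tRNA-Pro	tRNA	15627	15696	L				70	0
CR	CR	15697	16588	H				892	0
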