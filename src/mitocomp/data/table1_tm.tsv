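name	class	start	stop	strand	start_codon	stop_class	anticodon	size	intergenic
tRNA-Phe	tRNA	1	69	H				69	0
12S	rRNA	70	1012	H				943	0
tRNA-Val	tRNA	1013	1084	H				72	0
16S	rRNA	1085	2777	H				1693	0
tRNA-Leu	tRNA	2778	2851	H			UAA	74	0
ND1	CDS	2852	3826	H	ATG	TAA		975	3
tRNA-Ile	tRNA	3830	3899	H			GAU	70	-1
tRNA-Gln	tRNA	3899	3969	L			UUG	71	-1
tRNA-Met	tRNA	3969	4037	H			CAU	69	0
ND2	CDS	4038	5083	H	ATG	TA+		1046	0
tRNA-Trp	tRNA	5084	5155	H				72	1
tRNA-Ala	tRNA	5157	5225	L				69	1
tRNA-Asn	tRNA	5227	5299	L				73	5
OL	OL	5305	5334	L				30	0
tRNA-Cys	tRNA	5335	5400	L				66	0
tRNA-Tyr	tRNA	5401	5470	L				70	1
COX1	CDS	5472	7067	H	GTG	TAA		1596	0
tRNA-Ser	tRNA	7068	7138	L			UGA	71	3
tRNA-Asp	tRNA	7142	7214	H				73	5
COX2	CDS	7220	7910	H	ATG	T++		691	0
tRNA-Lys	tRNA	7911	7984	H				74	1
ATP8	CDS	7986	8153	H	ATG	TAA		168	-10
ATP6	CDS	8144	8826	H	ATG	TA+		683	0
COX3	CDS	8827	9610	H	ATG	T++		784	0
tRNA-Gly	tRNA	9611	9682	H				72	0
ND3	CDS	9683	10031	H	ATG	T++		349	0
tRNA-Arg	tRNA	10032	10100	H				69	0
ND4L	CDS	10101	10397	H	ATG	TAA		297	-7
ND4	CDS	10391	11771	H	ATG	T++		1381	0
tRNA-His	tRNA	11772	11840	H				69	0
tRNA-Ser2	tRNA	11841	11907	H			GCU	67	4
tRNA-Leu2	tRNA	11912	11984	H			UAG	73	0
ND5	CDS	11985	13823	H	ATG	TAA		1839	-4
ND6	CDS	13820	14341	L	ATG	TAA		522	0
tRNA-Glu	tRNA	14342	14410	L				69	4
CYTB	CDS	14415	15555	H	ATG	T++		1141	0
tRNA-Thr	tRNA	15556	15627	H				72	0
tRNA-Pro	tRNA	15628	15697	L				70	0
CR	CR	15698	16590	H				893	0
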